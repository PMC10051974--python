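"""Independent ImageJ ``.roi`` polygon encoder used as a test oracle.

Writes the binary layout directly (big-endian, 64-byte header, magic "Iout",
type byte 0 = polygon, bounding box at bytes 8-15, n_coordinates at 16-17,
then x offsets and y offsets as signed 16-bit integers relative to the
bounding-box left/top corner). Deliberately shares no code with the package
reader.
"""

import struct


def encode_polygon_roi(vertices, roi_type: int = 0) -> bytes:
    xs = [int(x) for x, _ in vertices]
    ys = [int(y) for _, y in vertices]
    left, top = min(xs), min(ys)
    right, bottom = max(xs), max(ys)
    header = bytearray(64)
    header[0:4] = b"Iout"
    struct.pack_into(">h", header, 4, 228)  # version
    header[6] = roi_type
    struct.pack_into(">hhhh", header, 8, top, left, bottom, right)
    struct.pack_into(">H", header, 16, len(xs))
    body = struct.pack(f">{len(xs)}h", *[x - left for x in xs])
    body += struct.pack(f">{len(ys)}h", *[y - top for y in ys])
    return bytes(header) + body
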