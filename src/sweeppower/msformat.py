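"""Reader/writer for ms-style haplotype output.

Each replicate is a block::

    //
    segsites: S
    positions: p1 p2 ... pS
    0100...            (one 0/1 line per chromosome)

Positions are fractions of the region length on [0, 1), printed with full
double precision so that write -> read round-trips bit-exactly.  A comment
line ``#focal pos=<fraction> freq=<float> col=<index|NA>`` directly after
``//`` carries the focal-site annotation and is preserved by the reader.
"""

from __future__ import annotations

import numpy as np

from .coalescent import FocalInfo, HaplotypeSample

__all__ = ["write_ms", "read_ms"]


def write_ms(samples, stream, L: float | None = None) -> None:
    """Write an iterable of :class:`HaplotypeSample` as ms-format blocks."""
    close = False
    if isinstance(stream, (str, bytes)):
        stream = open(stream, "w")
        close = True
    try:
        first = True
        for s in samples:
            if first:
                first = False
            else:
                stream.write("\n")
            stream.write("//\n")
            if s.focal is not None:
                col = "NA" if s.focal.column is None else str(s.focal.column)
                stream.write(
                    f"#focal pos={float(s.focal.position / s.L)!r} "
                    f"freq={float(s.focal.pop_freq)!r} col={col}\n"
                )
            stream.write(f"segsites: {s.S}\n")
            if s.S:
                fracs = " ".join(repr(float(p / s.L)) for p in s.positions)
                stream.write(f"positions: {fracs}\n")
                for row in s.matrix:
                    stream.write("".join("1" if v else "0" for v in row) + "\n")
    finally:
        if close:
            stream.close()


def read_ms(stream, L: float, n: int | None = None):
    """Parse ms-format blocks into :class:`HaplotypeSample` objects.

    ``L`` restores bp coordinates from fractional positions.  ``n`` (the
    number of chromosome lines per block) is required only for S = 0 blocks
    written by other simulators without padding lines.
    """
    close = False
    if isinstance(stream, (str, bytes)):
        stream = open(stream)
        close = True
    try:
        lines = stream.read().splitlines()
    finally:
        if close:
            stream.close()

    samples = []
    i = 0
    while i < len(lines):
        if lines[i].strip() != "//":
            i += 1
            continue
        i += 1
        focal = None
        if i < len(lines) and lines[i].startswith("#focal"):
            parts = dict(kv.split("=", 1) for kv in lines[i].split()[1:])
            col = None if parts["col"] == "NA" else int(parts["col"])
            focal = FocalInfo(
                position=float(parts["pos"]) * L,
                pop_freq=float(parts["freq"]),
                n_derived=-1,  # refined below from the matrix when possible
                column=col,
            )
            i += 1
        if i >= len(lines) or not lines[i].startswith("segsites:"):
            raise ValueError(f"line {i + 1}: expected 'segsites:'")
        S = int(lines[i].split(":", 1)[1])
        i += 1
        if S:
            if not lines[i].startswith("positions:"):
                raise ValueError(f"line {i + 1}: expected 'positions:'")
            fracs = np.array([float(x) for x in lines[i].split()[1:]])
            if len(fracs) != S:
                raise ValueError(f"line {i + 1}: {len(fracs)} positions for segsites {S}")
            i += 1
            rows = []
            while i < len(lines) and lines[i].strip() and set(lines[i].strip()) <= {"0", "1"}:
                rows.append([int(c) for c in lines[i].strip()])
                i += 1
            matrix = np.array(rows, dtype=np.uint8)
            positions = fracs * L
        else:
            matrix = np.zeros((n if n is not None else 0, 0), np.uint8)
            positions = np.empty(0)
        if focal is not None and focal.column is not None:
            focal = FocalInfo(
                position=focal.position, pop_freq=focal.pop_freq,
                n_derived=int(matrix[:, focal.column].sum()), column=focal.column,
            )
        samples.append(HaplotypeSample(matrix=matrix, positions=positions, L=L, focal=focal))
    return samples
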