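"""Tucson (RWL) ring-width file format.

Decadal layout: each line carries a series id (8 columns), the year of the first
value on the line, then up to ten yearly values.  Two dialects are recognised on
read: 0.01 mm units terminated by 999, and 0.001 mm units terminated by -9999.
Writing uses the 0.01 mm dialect.
"""

from __future__ import annotations

import numpy as np

__all__ = ["read_rwl", "write_rwl"]


def write_rwl(path, series: dict[str, tuple[int, np.ndarray]]) -> None:
    """Write ring-width series (mm) as {series_id: (first_year, values)}."""
    with open(path, "w") as fh:
        for sid, (first_year, values) in series.items():
            if len(sid) > 8:
                raise ValueError(f"series id {sid!r} longer than 8 characters")
            vals = [int(round(v * 100)) for v in values]
            year = first_year
            pos = 0
            while pos < len(vals):
                decade_end = (year // 10) * 10 + 9
                chunk = vals[pos : pos + (decade_end - year + 1)]
                line = f"{sid:<8}{year:>4}" + "".join(f"{v:>6}" for v in chunk)
                pos += len(chunk)
                year = decade_end + 1
                if pos == len(vals):
                    line += f"{999:>6}"
                fh.write(line + "\n")


def read_rwl(path) -> dict[str, tuple[int, np.ndarray]]:
    """Read a Tucson file, auto-detecting the 0.01 mm / 0.001 mm dialect."""
    raw: dict[str, list[tuple[int, list[int]]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            sid = line[:8].strip()
            tokens = line[8:].split()
            if len(tokens) < 2:
                continue
            try:
                year = int(tokens[0])
                vals = [int(t) for t in tokens[1:]]
            except ValueError:
                continue  # header lines of some producers
            raw.setdefault(sid, []).append((year, vals))

    out: dict[str, tuple[int, np.ndarray]] = {}
    for sid, lines in raw.items():
        flat: list[int] = []
        first_year = lines[0][0]
        terminated = None
        for year, vals in lines:
            for v in vals:
                if v == 999 and terminated is None:
                    terminated = "999"
                    break
                if v == -9999:
                    terminated = "-9999"
                    break
                flat.append(v)
            if terminated:
                break
        scale = 0.001 if terminated == "-9999" else 0.01
        out[sid] = (first_year, np.array(flat, dtype=float) * scale)
    return out
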