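"""Loaders for externally published data formats.

Currently: dadi-style frequency-spectrum files, used for the published
three-population joint SFS (axes ordered YRI, CEU, CHB at 20 sampled
chromosomes each in the original distribution).  These files must be
obtained from the source study's distribution; nothing is bundled here.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import FormatError

__all__ = ["load_dadi_fs"]


def load_dadi_fs(path: str | Path) -> np.ndarray:
    """Parse a dadi .fs file into a dense array (monomorphic corners kept).

    Format: an optional comment block, a header line with the per-axis
    shape (sample size + 1 per population) and optional folding token,
    the whitespace-separated values, and an optional trailing mask line.
    """
    tokens_lines = [
        ln for ln in Path(path).read_text().splitlines() if not ln.startswith("#")
    ]
    if not tokens_lines:
        raise FormatError(f"empty fs file: {path}")
    header = tokens_lines[0].split()
    shape = []
    for tok in header:
        try:
            shape.append(int(tok))
        except ValueError:
            break
    if not shape:
        raise FormatError(f"no shape information in fs header: {header!r}")
    size = int(np.prod(shape))
    flat: list[float] = []
    for ln in tokens_lines[1:]:
        for tok in ln.split():
            try:
                flat.append(float(tok))
            except ValueError:
                raise FormatError(f"non-numeric fs entry {tok!r}") from None
        if len(flat) >= size:
            break
    if len(flat) < size:
        raise FormatError(
            f"fs file holds {len(flat)} values, expected {size} for shape {shape}"
        )
    return np.array(flat[:size]).reshape(shape)
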