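"""Texture-matrix container shared by the five matrix families."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class TextureMatrix:
    """Raw (unnormalized) count matrix of one texture family.

    For direction-dependent families (GLCM, GLRLM) ``entries`` carries a
    leading direction axis; direction-free families (GLSZM, GLDM) store a
    single 2-D matrix and NGTDM stores its ``s_i``/``n_i`` columns.
    """

    kind: str
    entries: np.ndarray
    normalized: bool = False

    def normalize(self) -> "TextureMatrix":
        """Scale each (per-direction) matrix to unit sum."""
        e = np.asarray(self.entries, dtype=float)
        if e.ndim == 3:  # direction-stacked
            totals = e.sum(axis=(1, 2), keepdims=True)
            out = np.divide(e, totals, out=np.zeros_like(e), where=totals > 0)
        else:
            total = e.sum()
            out = e / total if total > 0 else np.zeros_like(e)
        return TextureMatrix(self.kind, out, normalized=True)
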