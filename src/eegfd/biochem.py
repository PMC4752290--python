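"""Non-ceruloplasmin-bound ("free") copper from a serum copper panel.

Ceruloplasmin carries six structural copper atoms — about 0.3% of its
mass — so the ceruloplasmin-bound copper (CB) in circulation is

    CB [umol/L] = ceruloplasmin [mg/dL] * 10 * 0.0472 [umol/mg]

(the factor 10 converts mg/dL to mg/L).  Non-ceruloplasmin copper is the
remainder of the absolute serum copper:

    NCC = serum copper - CB        (all in umol/L)

Assay noise can push NCC slightly negative; such values are preserved and
flagged with a warning rather than clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["COPPER_PER_CERULOPLASMIN_UMOL_PER_MG", "CopperPanel", "compute_ncc"]

#: Structural copper content of ceruloplasmin, umol of Cu per mg of protein.
COPPER_PER_CERULOPLASMIN_UMOL_PER_MG = 0.0472


@dataclass(frozen=True)
class CopperPanel:
    """Serum copper panel with the derived bound and free fractions.

    ``serum_copper`` and the derived ``cb``/``ncc`` are in umol/L;
    ``ceruloplasmin`` is in mg/dL.
    """

    serum_copper: float
    ceruloplasmin: float
    cb: float
    ncc: float


def compute_ncc(serum_copper: float, ceruloplasmin: float) -> CopperPanel:
    """Derive ceruloplasmin-bound and non-ceruloplasmin copper.

    Parameters
    ----------
    serum_copper
        Absolute serum copper, umol/L (non-negative, finite).
    ceruloplasmin
        Ceruloplasmin concentration, mg/dL (non-negative, finite).
    """
    if not (np.isfinite(serum_copper) and np.isfinite(ceruloplasmin)):
        raise ValueError("copper panel inputs must be finite")
    if serum_copper < 0 or ceruloplasmin < 0:
        raise ValueError(
            f"copper panel inputs must be non-negative, got "
            f"serum_copper={serum_copper}, ceruloplasmin={ceruloplasmin}"
        )
    cb = ceruloplasmin * 10.0 * COPPER_PER_CERULOPLASMIN_UMOL_PER_MG
    ncc = serum_copper - cb
    if ncc < 0:
        logger.warning(
            "negative NCC %.4g umol/L (serum %.4g, CB %.4g): kept, not clipped",
            ncc, serum_copper, cb,
        )
    return CopperPanel(
        serum_copper=float(serum_copper),
        ceruloplasmin=float(ceruloplasmin),
        cb=float(cb),
        ncc=float(ncc),
    )
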