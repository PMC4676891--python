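"""Inter-observer and inter-method agreement statistics.

Percent agreement, Cohen's kappa (with two within-tolerance variants for
continuous grades such as cup:disc ratios) and Bland-Altman 95% limits of
agreement.  Kappa point estimates carry the conventional Landis-Koch verbal
labels in reports.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "cohen_kappa",
    "kappa_within_tolerance",
    "bland_altman",
    "proportion_within",
    "kappa_label",
]


def cohen_kappa(cross_table) -> float:
    """Cohen's kappa from a square rater-by-rater cross table.

    kappa = (p_o - p_e) / (1 - p_e) with chance agreement p_e from the
    marginal products; defined as 1 when observed and chance agreement are
    both perfect.
    """
    table = np.asarray(cross_table, dtype=float)
    if table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise ValueError(f"cross table must be square, got shape {table.shape}")
    total = table.sum()
    if total < 1:
        raise ValueError("cross table is empty")
    p_o = np.trace(table) / total
    p_e = float(np.sum(table.sum(axis=0) * table.sum(axis=1)) / total ** 2)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1 - p_e))


def _check_pairs(pairs) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(pairs, dtype=float)
    if arr.size == 0:
        raise ValueError("no rating pairs supplied")
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of ratings")
    return arr[:, 0], arr[:, 1]


def kappa_within_tolerance(pairs, delta: float,
                           method: str = "binned") -> float:
    """Chance-corrected agreement of continuous ratings within ``delta``.

    ``method="binned"`` (default): values are binned into delta-width bins
    and Cohen's kappa computed on the binned square table, so "agreement"
    means landing in the same bin.  ``method="tolerance"``: observed
    agreement is the fraction of pairs with |a-b| <= delta and chance
    agreement is the probability of that event under independent raters
    (cross product of the two empirical distributions).
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    a, b = _check_pairs(pairs)
    if method == "binned":
        bins_a = np.floor(a / delta + 1e-9).astype(int)
        bins_b = np.floor(b / delta + 1e-9).astype(int)
        lo = min(bins_a.min(), bins_b.min())
        hi = max(bins_a.max(), bins_b.max())
        k = hi - lo + 1
        table = np.zeros((k, k))
        np.add.at(table, (bins_a - lo, bins_b - lo), 1)
        return cohen_kappa(table)
    if method == "tolerance":
        p_o = np.mean(np.abs(a - b) <= delta + 1e-12)
        va, ca = np.unique(a, return_counts=True)
        vb, cb = np.unique(b, return_counts=True)
        pa, pb = ca / ca.sum(), cb / cb.sum()
        within = np.abs(va[:, None] - vb[None, :]) <= delta + 1e-12
        p_e = float(pa @ within @ pb)
        if p_e == 1.0:
            return 1.0 if p_o == 1.0 else 0.0
        return float((p_o - p_e) / (1 - p_e))
    raise ValueError(f"unknown method {method!r}")


def bland_altman(pairs) -> tuple[float, float, float]:
    """Bland-Altman bias and 95% limits of agreement.

    Returns (bias, lower limit, upper limit) where bias = mean(a - b) and
    the limits are bias +/- 1.96 x SD(a - b).
    """
    a, b = _check_pairs(pairs)
    if len(a) < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def proportion_within(pairs, delta: float) -> float:
    """Percent of pairs whose absolute difference is at most ``delta``."""
    if delta < 0:
        raise ValueError("delta must be non-negative")
    a, b = _check_pairs(pairs)
    return float(100.0 * np.mean(np.abs(a - b) <= delta + 1e-12))


def kappa_label(kappa: float) -> str:
    """Landis-Koch verbal strength-of-agreement label."""
    if kappa < 0:
        return "poor"
    for bound, label in ((0.20, "slight"), (0.40, "fair"), (0.60, "moderate"),
                         (0.80, "substantial")):
        if kappa <= bound:
            return label
    return "almost perfect"
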