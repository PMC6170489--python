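"""Goodness-of-fit and model-selection statistics.

Reduced chi-square uses a single scalar squared measurement error:

    chi2_red = SSR / (f * dy2),   f = n - p.

For measured PET data the per-frame error is approximated by counting
statistics, dy ~ sqrt(y), collapsed to the scalar dy2 = mean(y); for
simulated data the noise level is known exactly, dy = sigma = AIF_peak/SNR.

Model comparison uses the Akaike information criterion and its small-sample
correction:

    AIC  = n ln(SSR / n) + 2 (p + 1)
    cAIC = AIC + 2 (p + 1)(p + 2) / (n - p - 2)

with the lowest cAIC designating the preferred model.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "reduced_chi2",
    "dy2_measured",
    "information_criteria",
    "select_model",
]


def dy2_measured(values: np.ndarray) -> float:
    """Scalar squared measurement error for a measured TAC (dy ~ sqrt(y))."""
    m = float(np.mean(np.asarray(values, dtype=float)))
    if m <= 0:
        raise ValueError("mean activity must be positive for the sqrt(y) error model")
    return m


def reduced_chi2(ssr: float, n: int, p: int, dy2: float) -> float:
    if n <= p:
        raise ValueError(f"degrees of freedom n - p = {n - p} must be positive")
    if dy2 <= 0:
        raise ValueError("dy2 must be positive")
    if ssr < 0:
        raise ValueError("ssr must be non-negative")
    return ssr / ((n - p) * dy2)


def information_criteria(ssr: float, n: int, p: int) -> tuple[float, float]:
    """(AIC, cAIC); SSR = 0 yields -inf with a warning (noiseless synthetic fits)."""
    if n <= p + 2:
        raise ValueError("cAIC requires n > p + 2")
    if ssr < 0:
        raise ValueError("ssr must be non-negative")
    if ssr == 0.0:
        warnings.warn("SSR = 0: information criteria are -inf", RuntimeWarning)
        return float("-inf"), float("-inf")
    aic = n * np.log(ssr / n) + 2 * (p + 1)
    caic = aic + 2 * (p + 1) * (p + 2) / (n - p - 2)
    return float(aic), float(caic)


def select_model(fits, dy2: float | None = None) -> tuple[str, pd.DataFrame]:
    """Pick the best model among fits of the *same* TAC by lowest cAIC.

    ``fits`` is a sequence of FitResult; ties go to the model with fewer
    parameters.  Returns (best model id, criteria table).
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits supplied")
    ns = {f.n_frames for f in fits}
    if len(ns) != 1:
        raise ValueError("fits compare different frame counts")
    n = ns.pop()
    rows = []
    for f in fits:
        aic, caic = information_criteria(f.ssr, n, f.n_params)
        row = {"model": f.params.model, "ssr": f.ssr, "p": f.n_params,
               "aic": aic, "caic": caic}
        if dy2 is not None:
            row["chi2_red"] = reduced_chi2(f.ssr, n, f.n_params, dy2)
        rows.append(row)
    table = pd.DataFrame(rows)
    order = table.sort_values(["caic", "p"], kind="stable")
    best = str(order.iloc[0]["model"])
    table["selected"] = table["model"] == best
    return best, table
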