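"""AICc multimodel inference over the candidate set.

AICc = −2·logLik + 2k + 2k(k+1)/(n−k−1); ΔAICc is measured against the
best candidate and Akaike weights are wAICc = exp(−Δ/2) normalized over
the whole candidate set. All candidates must be fit on the identical
record set for the likelihoods to be comparable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["aicc", "rank_models", "format_ranking"]


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k == 0:
        return -2.0 * loglik
    if n <= k + 1:
        raise ValueError(
            f"AICc undefined for n={n}, k={k}: requires n > k + 1"
        )
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def rank_models(fits) -> pd.DataFrame:
    """Rank fitted candidates by AICc and attach ΔAICc and Akaike weights.

    Returns a DataFrame sorted ascending by AICc with columns
    (model, variance, fixed_effects, k, n, loglik, aicc, delta_aicc, waicc).
    Ties are broken by smaller k, then by model label. Raises on an empty
    input or on candidates fit to different record sets (mixed n).
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fitted models to rank")
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise ValueError(
            f"candidates were fit on different record sets (n = {sorted(ns)}); "
            "AICc values are not comparable"
        )
    rows = []
    for f in fits:
        if not np.isfinite(f.aicc):
            raise ValueError(f"model {f.spec.label} has no finite AICc")
        rows.append(
            {
                "model": f.spec.label,
                "variance": f.spec.variance,
                "fixed_effects": f.spec.fixed_effects,
                "k": f.k,
                "n": f.n,
                "loglik": f.loglik,
                "aicc": f.aicc,
                "converged": f.converged,
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["aicc", "k", "model"], kind="mergesort"
    ).reset_index(drop=True)
    table["delta_aicc"] = table["aicc"] - table["aicc"].iloc[0]
    rel = np.exp(-0.5 * table["delta_aicc"].to_numpy())
    table["waicc"] = rel / rel.sum()
    return table


def format_ranking(table: pd.DataFrame, decimals: int = 2) -> str:
    """Plain-text report of a ranking table, AICc columns at 2 decimals."""
    out = table.copy()
    for col in ("loglik", "aicc", "delta_aicc"):
        out[col] = out[col].map(lambda v: f"{v:.{decimals}f}")
    out["waicc"] = out["waicc"].map(lambda v: f"{v:.3f}")
    cols = ["model", "fixed_effects", "k", "loglik", "aicc", "delta_aicc", "waicc"]
    return out[cols].to_string(index=False)
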