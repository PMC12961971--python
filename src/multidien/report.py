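"""Cohort-level summaries and population sign-test tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import correlation, sign_test_two_tailed


def tukey_hinges(values) -> tuple[float, float, float]:
    """(lower hinge, median, upper hinge) by the midpoint-of-halves rule.

    The sample is sorted and split at the median (the median itself joins
    both halves for odd n); each half's median is its hinge, with the
    midpoint of the central pair used for even-length halves.
    """
    x = np.sort(np.asarray(values, float))
    n = len(x)
    if n == 0:
        raise ValueError("empty sample")

    def _median(v: np.ndarray) -> float:
        m = len(v)
        if m == 0:
            raise ValueError("empty half")
        return float(v[m // 2]) if m % 2 else float(
            (v[m // 2 - 1] + v[m // 2]) / 2.0
        )

    if n == 1:
        return float(x[0]), float(x[0]), float(x[0])
    lower = x[: (n + 1) // 2]
    upper = x[n // 2:]
    return _median(lower), _median(x), _median(upper)


def summarize_cohort(
    frame: pd.DataFrame,
    plv_col: str = "le_plv",
    period_col: str = "cycle_period_days",
) -> dict:
    """Median and quartiles of the LE PLV and cycle-period columns, cohort
    means/SDs, and the Spearman correlation between period and PLV."""
    if len(frame) == 0:
        raise ValueError("empty cohort")
    out: dict = {"n": int(len(frame))}
    for key, col in (("plv", plv_col), ("period", period_col)):
        vals = frame[col].astype(float).to_numpy()
        lo, med, hi = tukey_hinges(vals)
        out[key] = {
            "median": med,
            "iqr": [lo, hi],
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        }
    if len(frame) >= 3:
        r, p = correlation(
            frame[period_col], frame[plv_col], kind="spearman"
        )
        out["period_plv_spearman"] = {"r": r, "p": p}
    return out


def sign_test_table(effect_records) -> pd.DataFrame:
    """Population sign tests of per-patient effect sizes.

    One row per (feature, contrast): counts of positive/negative effects
    across patients (zeros dropped) and the exact two-tailed sign-test p.
    """
    df = pd.DataFrame(
        [
            {
                "feature": r.feature,
                "contrast": r.contrast,
                "cohens_d": r.cohens_d,
            }
            for r in effect_records
        ]
    )
    rows = []
    for (feature, contrast), grp in df.groupby(["feature", "contrast"]):
        d = grp["cohens_d"].to_numpy()
        d = d[np.isfinite(d)]
        n_pos = int((d > 0).sum())
        n_neg = int((d < 0).sum())
        rows.append(
            {
                "feature": feature,
                "contrast": contrast,
                "n_pos": n_pos,
                "n_neg": n_neg,
                "median_d": float(np.median(d)) if d.size else np.nan,
                "p": sign_test_two_tailed(n_pos, n_neg)
                if n_pos + n_neg
                else np.nan,
            }
        )
    return pd.DataFrame(rows)
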