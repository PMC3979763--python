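"""MA-plot random-sampling differential expression.

The test models each gene's count in a sample as a binomial draw
C ~ Bin(n, p) from the library (the "random sampling" assumption). With
X = log2 C1, Y = log2 C2, M = X - Y and A = (X + Y)/2, the delta method gives
X ~ N(log2(n1 p), (1-p)/(n1 p ln^2 2)) and likewise Y; conditioning the
resulting bivariate normal on A yields

    E(M | A=a) = (muX - muY) + 2 (sX2 - sY2)/(sX2 + sY2) * (a - (muX + muY)/2)
    Var(M | A) = 4 sX2 sY2 / (sX2 + sY2)

with the pooled null estimate p = (c1 + c2)/(n1 + n2). The standardized
z = (M - E(M|A)) / sqrt(Var(M|A)) is referred to the normal two-sided tail.
These conditional moments are the analytically exact conditioning of
independent normals (Cov(M, A) = (sX2 - sY2)/2, Var(A) = (sX2 + sY2)/4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ma_test",
    "ma_test_table",
    "bh_adjust",
    "call_de",
    "fold_change_correlation",
]

_LN2_SQ = np.log(2.0) ** 2


def ma_test(c1, c2, n1: float, n2: float) -> pd.DataFrame:
    """MA-plot binomial random-sampling test for counts c1 (treated) vs c2
    (control) with library sizes n1, n2.

    Accepts scalars or arrays; returns a DataFrame with columns
    ``M, A, p_hat, mu_M, var_M, z, p, zero_flagged, untested``.

    Zero handling: if both counts are zero the gene is untested (all-NaN
    statistics); if exactly one is zero it is replaced by 0.5 before the
    logs and the gene is flagged (``zero_flagged``).
    """
    c1 = np.atleast_1d(np.asarray(c1, dtype=np.float64))
    c2 = np.atleast_1d(np.asarray(c2, dtype=np.float64))
    if c1.shape != c2.shape:
        raise ValueError("c1 and c2 must have the same shape")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    if (c1 > n1).any() or (c2 > n2).any():
        raise ValueError("counts cannot exceed library sizes")
    if (c1 < 0).any() or (c2 < 0).any():
        raise ValueError("counts must be >= 0")

    untested = (c1 == 0) & (c2 == 0)
    flagged = ((c1 == 0) ^ (c2 == 0)) & ~untested
    a1 = np.where(c1 == 0, 0.5, c1)
    a2 = np.where(c2 == 0, 0.5, c2)

    p_hat = (a1 + a2) / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.log2(a1)
        y = np.log2(a2)
        mu_x = np.log2(n1 * p_hat)
        mu_y = np.log2(n2 * p_hat)
        s2x = (1.0 - p_hat) / (n1 * p_hat * _LN2_SQ)
        s2y = (1.0 - p_hat) / (n2 * p_hat * _LN2_SQ)
        m = x - y
        a = (x + y) / 2.0
        mu_m = (mu_x - mu_y) + 2.0 * (s2x - s2y) / (s2x + s2y) * (a - (mu_x + mu_y) / 2.0)
        var_m = 4.0 * s2x * s2y / (s2x + s2y)
        z = (m - mu_m) / np.sqrt(var_m)
    p = 2.0 * stats.norm.sf(np.abs(z))

    out = pd.DataFrame(
        {
            "M": m,
            "A": a,
            "p_hat": p_hat,
            "mu_M": mu_m,
            "var_M": var_m,
            "z": z,
            "p": p,
            "zero_flagged": flagged,
            "untested": untested,
        }
    )
    out.loc[untested, ["M", "A", "p_hat", "mu_M", "var_M", "z", "p"]] = np.nan
    return out


def ma_test_table(
    counts, treated: str, control: str
) -> pd.DataFrame:
    """Run :func:`ma_test` on two samples of a :class:`CountTable`."""
    c1 = counts.counts[treated].to_numpy()
    c2 = counts.counts[control].to_numpy()
    n1 = float(counts.library_size[treated])
    n2 = float(counts.library_size[control])
    res = ma_test(c1, c2, n1, n2)
    res.index = counts.counts.index
    res.attrs["n1"], res.attrs["n2"] = n1, n2
    return res


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (q-values), NaN passthrough."""
    p = np.asarray(pvalues, dtype=np.float64)
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def call_de(
    day2: pd.DataFrame,
    day4: pd.DataFrame,
    fdr: float = 0.001,
    fc: float = 1.5,
) -> pd.DataFrame:
    """Composite two-timepoint DE call.

    A gene is called up/down iff (i) its day-2 BH q-value is below ``fdr``,
    (ii) its library-size-adjusted day-2 fold change is at least ``fc``
    (|M - log2(n1/n2)| >= log2 fc), and (iii) the adjusted fold change has
    the same non-zero sign on day 4. "Up" means higher in the treated
    (silenced) condition. Day 4 contributes only the direction; genes
    untested on either day are ``untested``.

    ``day2``/``day4`` are :func:`ma_test_table` outputs on a matched gene
    universe (library sizes read from ``.attrs``).
    """
    if not day2.index.equals(day4.index):
        raise ValueError("day2 and day4 must share the same gene universe")

    def adj(df: pd.DataFrame) -> pd.Series:
        offset = np.log2(df.attrs["n1"] / df.attrs["n2"]) if "n1" in df.attrs else 0.0
        return df["M"] - offset

    m2, m4 = adj(day2), adj(day4)
    q2 = pd.Series(bh_adjust(day2["p"]), index=day2.index)
    untested = day2["untested"] | day4["untested"]
    log2fc = np.log2(fc)

    passes = (
        (q2 < fdr)
        & (m2.abs() >= log2fc)
        & (np.sign(m2) == np.sign(m4))
        & (np.sign(m2) != 0)
        & ~untested
    )
    status = pd.Series("not_de", index=day2.index, dtype=object)
    status[untested] = "untested"
    status[passes & (m2 > 0)] = "up"
    status[passes & (m2 < 0)] = "down"
    return pd.DataFrame(
        {"status": status, "M_day2": m2, "M_day4": m4, "q_day2": q2}
    )


def fold_change_correlation(fc_a, fc_b) -> tuple[float, float]:
    """Pearson correlation of paired per-gene fold changes with its t-test.

    Returns (r, two-sided p) where p comes from t = r sqrt((n-2)/(1-r^2))
    on n-2 degrees of freedom. Non-finite pairs are dropped; fewer than 3
    finite pairs or zero variance raise ValueError.
    """
    a = np.asarray(fc_a, dtype=np.float64)
    b = np.asarray(fc_b, dtype=np.float64)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ValueError("need at least 3 paired finite values")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined: zero variance")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
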