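"""Counting, TMM normalization, and replicate-free differential expression.

Counts per product (mature and star are separate rows) are normalized with
the trimmed-mean-of-M-values (TMM) factor and expressed as reads per
million effective library size::

    normalized = raw / (library_size * factor) * 1e6

Differential expression between the two libraries uses an exact test under
the Poisson assumption for technical variation without biological
replicates: conditional on the total n = k1 + k2, k1 is Binomial(n, p0)
with p0 = s1/(s1+s2) set by the effective library sizes, and the two-sided
p-value sums binomial probabilities not exceeding that of the observed
count.  A product is called up or down when the normalized fold change
strictly exceeds the threshold (default 2-fold) and p < 0.001.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEResult",
    "build_counts",
    "tmm_factor",
    "tmm_pair_factors",
    "normalize",
    "de_test",
    "call_de",
]


@dataclass(frozen=True)
class DEResult:
    product_id: str
    raw_f3: int
    raw_f4: int
    norm_f3: float
    norm_f4: float
    log2fc: float  # log2(norm F3 / norm F4); positive = higher in F3 (castrated)
    pvalue: float
    call: str  # up | down | ns


def build_counts(assignments: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Product x library count matrix from per-isomiR assignments.

    *assignments* needs columns product_id, count_f3, count_f4 (one row per
    isomiR).  Returns the summed matrix and the library sizes (column
    sums).  Mature and star products are independent rows by construction
    of their product ids.
    """
    if assignments.empty:
        raise ValueError("no assignments; cannot build a count matrix")
    mat = (
        assignments.groupby("product_id")[["count_f3", "count_f4"]]
        .sum()
        .astype(int)
        .rename(columns={"count_f3": "raw_f3", "count_f4": "raw_f4"})
    )
    lib_sizes = mat.sum()
    lib_sizes.index = ["F3", "F4"]
    return mat, lib_sizes


def tmm_factor(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> float:
    """TMM scaling factor of library *a* relative to reference *b*.

    M (log2 ratio of library-size-scaled proportions) and A (average log2
    abundance) are computed over genes positive in both libraries; the top
    and bottom ``trim_m`` of M and ``trim_a`` of A are trimmed; the factor
    is 2 to the precision-weighted mean of the remaining M values, with
    weights from the delta-method binomial variance.  With no
    doubly-positive genes the factor is 1.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must have equal length")
    na, nb = a.sum(), b.sum()
    if na <= 0 or nb <= 0:
        raise ValueError("library sizes must be positive")
    keep = (a > 0) & (b > 0)
    if not keep.any():
        return 1.0
    a, b = a[keep], b[keep]
    pa, pb = a / na, b / nb
    m = np.log2(pa / pb)
    avg = 0.5 * (np.log2(pa) + np.log2(pb))
    # asymptotic (delta-method) inverse variance of M
    w = 1.0 / ((na - a) / (na * a) + (nb - b) / (nb * b))

    n = len(m)
    lo_m, hi_m = math.floor(n * trim_m) + 1, n + 1 - (math.floor(n * trim_m) + 1)
    lo_a, hi_a = math.floor(n * trim_a) + 1, n + 1 - (math.floor(n * trim_a) + 1)
    rank_m = stats.rankdata(m, method="average")
    rank_a = stats.rankdata(avg, method="average")
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any() or w[keep2].sum() == 0:
        return 1.0
    f = (w[keep2] * m[keep2]).sum() / w[keep2].sum()
    return float(2.0 ** f)


def tmm_pair_factors(
    counts_f3: np.ndarray, counts_f4: np.ndarray, **kw
) -> tuple[float, float]:
    """Per-library TMM factors scaled so their geometric mean is 1."""
    f3 = tmm_factor(counts_f3, counts_f4, **kw)
    f4 = 1.0
    g = math.sqrt(f3 * f4)
    return f3 / g, f4 / g


def normalize(raw: float, library_size: float, factor: float) -> float:
    """normalized read counts = raw / (library_size * factor) * 1e6."""
    if library_size <= 0:
        raise ValueError("library size must be positive")
    if factor <= 0:
        raise ValueError("normalization factor must be positive")
    return raw / (library_size * factor) * 1e6


_EXACT_N_MAX = 100_000


def de_test(k1: int, k2: int, s1: float, s2: float) -> float:
    """Two-sided exact test of equal (size-adjusted) Poisson rates.

    Conditional on n = k1 + k2, k1 ~ Binomial(n, p0) with
    p0 = s1 / (s1 + s2).  For very large n a normal approximation with
    continuity correction is used; it agrees with the exact tail to three
    significant figures well below the switch point.
    """
    if k1 < 0 or k2 < 0:
        raise ValueError("counts must be non-negative")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("effective library sizes must be positive")
    n = k1 + k2
    if n == 0:
        return 1.0
    p0 = s1 / (s1 + s2)
    if n <= _EXACT_N_MAX:
        return float(stats.binomtest(k1, n, p0, alternative="two-sided").pvalue)
    mu, sd = n * p0, math.sqrt(n * p0 * (1 - p0))
    z = (abs(k1 - mu) - 0.5) / sd
    p = 2.0 * stats.norm.sf(max(z, 0.0))
    return float(min(p, 1.0))


def call_de(
    counts: pd.DataFrame,
    lib_sizes: pd.Series | None = None,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.001,
    pseudocount: float = 0.5,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.DataFrame:
    """Full DE table for a product x {raw_f3, raw_f4} count matrix.

    TMM factors are computed on the matrix itself; effective library size
    is column sum x factor.  The fold change is computed on normalized
    counts, with *pseudocount* added to both normalized values only when
    either raw count is zero (a display convention — the exact test handles
    zeros natively).  Calls require |log2fc| > log2(fc_threshold) strictly
    and p < p_threshold strictly.  The returned frame also carries the
    scatter columns log2_norm_f3 / log2_norm_f4.
    """
    raw3 = counts["raw_f3"].to_numpy()
    raw4 = counts["raw_f4"].to_numpy()
    if lib_sizes is None:
        lib_sizes = pd.Series(
            {"F3": int(raw3.sum()), "F4": int(raw4.sum())}
        )
    f3_factor, f4_factor = tmm_pair_factors(raw3, raw4, trim_m=trim_m, trim_a=trim_a)
    s3 = lib_sizes["F3"] * f3_factor
    s4 = lib_sizes["F4"] * f4_factor
    lfc_gate = math.log2(fc_threshold)

    rows = []
    for pid, k1, k2 in zip(counts.index, raw3, raw4):
        n3 = normalize(k1, lib_sizes["F3"], f3_factor)
        n4 = normalize(k2, lib_sizes["F4"], f4_factor)
        if k1 == 0 or k2 == 0:
            lfc = math.log2((n3 + pseudocount) / (n4 + pseudocount))
        else:
            lfc = math.log2(n3 / n4)
        p = de_test(int(k1), int(k2), s3, s4)
        if abs(lfc) > lfc_gate and p < p_threshold:
            call = "up" if lfc > 0 else "down"
        else:
            call = "ns"
        rows.append(
            {
                "product_id": pid,
                "raw_f3": int(k1),
                "raw_f4": int(k2),
                "norm_f3": n3,
                "norm_f4": n4,
                "log2fc": lfc,
                "pvalue": p,
                "call": call,
                "log2_norm_f3": math.log2(n3 + pseudocount),
                "log2_norm_f4": math.log2(n4 + pseudocount),
            }
        )
    df = pd.DataFrame(rows).set_index("product_id")
    df.attrs["tmm_factors"] = {"F3": f3_factor, "F4": f4_factor}
    return df
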