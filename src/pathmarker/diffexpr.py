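"""Differential expression by a negative-binomial exact test.

Tumor and normal read counts are compared gene by gene under an NB model
with mean mu and variance mu + phi*mu**2 (dispersion phi >= 0; phi = 0 is
the Poisson limit).  After scaling both groups to a common library size,
the two group totals are compared conditionally on their sum: the two-sided
p-value sums the probabilities of every split of the total that is no more
probable than the observed one.  Genes are called differentially expressed
when p < 0.05 and the tumor/normal fold change of mean CPM is > 2 or < 0.5
(both inequalities strict).

Dispersion is estimated by the method of moments per gene and shrunk toward
the common (across-gene) value; the full conditional-maximum-likelihood /
empirical-Bayes machinery of dedicated DE packages is intentionally not
reproduced — the exact test itself is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "CountMatrix",
    "DispersionEstimate",
    "load_counts",
    "normalize",
    "cpm",
    "estimate_dispersion",
    "exact_test",
    "de_table",
    "call_degs",
    "write_deg_table",
]

TUMOR, NORMAL = "tumor", "normal"


# ---------------------------------------------------------------------------
# count container
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Genes x samples integer read counts with tumor/normal labels.

    ``counts`` is a pandas DataFrame indexed by gene id with sample-id
    columns; ``labels`` is a Series over the same samples taking values
    ``"tumor"`` / ``"normal"``.  Library sizes are the column sums.
    """

    counts: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.counts.columns)
        if self.labels.isna().any():
            missing = list(self.labels[self.labels.isna()].index[:5])
            raise ValueError(f"samples without labels: {missing}")
        bad = set(self.labels.unique()) - {TUMOR, NORMAL}
        if bad:
            raise ValueError(f"labels must be tumor/normal, got {sorted(bad)}")
        values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def group_columns(self, group: str) -> pd.Index:
        return self.samples[self.labels == group]


def load_counts(counts_path: str | Path, labels_path: str | Path) -> CountMatrix:
    """Read a counts TSV (first column gene id) and a sample-label TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    lab = pd.read_csv(
        labels_path, sep="\t", header=None, names=["sample", "label"], comment="#"
    )
    labels = pd.Series(lab["label"].values, index=lab["sample"].values)
    return CountMatrix(counts=counts, labels=labels)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize(counts: CountMatrix, method: str = "libsize") -> pd.Series:
    """Per-sample normalization factors, geometric mean one.

    ``libsize``
        factor proportional to the column sum (total count), centred to
        geometric mean 1; equal libraries therefore all get factor 1.
    ``tmm``
        trimmed mean of M-values against a reference column: gene-wise
        log2 ratios (M) and mean log2 abundances (A) are computed on
        library-size-scaled counts, genes in the top/bottom 30% of M or
        5% of A are trimmed, and the factor is 2**mean(remaining M).
        An unweighted trimmed mean is used.
    """
    lib = counts.library_sizes.astype(float)
    if (lib <= 0).all():
        raise ValueError("all libraries are empty")
    if (lib <= 0).any():
        raise ValueError("every sample needs a nonzero library for normalization")

    if method == "libsize":
        factors = lib / np.exp(np.mean(np.log(lib)))
    elif method == "tmm":
        mat = counts.counts.to_numpy(dtype=float)
        prop = mat / lib.to_numpy()
        # reference: sample whose upper-quartile proportion is closest to the mean
        uq = np.array([np.quantile(prop[:, j][mat[:, j] > 0], 0.75)
                       if (mat[:, j] > 0).any() else 0.0
                       for j in range(mat.shape[1])])
        ref = int(np.argmin(np.abs(uq - uq.mean())))
        raw = np.ones(mat.shape[1])
        for j in range(mat.shape[1]):
            if j == ref:
                continue
            raw[j] = 2.0 ** _tmm_log_ratio(mat[:, j], lib.iloc[j],
                                           mat[:, ref], lib.iloc[ref])
        factors = raw / np.exp(np.mean(np.log(raw)))
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return pd.Series(factors, index=counts.samples, name="norm_factor")


def _tmm_log_ratio(
    obs: np.ndarray,
    lib_obs: float,
    ref: np.ndarray,
    lib_ref: float,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
) -> float:
    """Doubly trimmed mean of gene-wise M values for one sample vs reference."""
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        return 0.0
    p_obs = obs[ok] / lib_obs
    p_ref = ref[ok] / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    keep = np.ones(m.size, dtype=bool)
    for values, trim in ((m, m_trim), (a, a_trim)):
        lo, hi = np.quantile(values, [trim, 1 - trim])
        keep &= (values >= lo) & (values <= hi)
    if not keep.any():
        return 0.0
    return float(np.mean(m[keep]))


def cpm(
    counts: CountMatrix,
    factors: pd.Series | None = None,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Counts per million on effective (factor-adjusted) library sizes."""
    if factors is None:
        factors = pd.Series(1.0, index=counts.samples)
    eff = counts.library_sizes.astype(float) * factors
    return (counts.counts + pseudocount) / eff.to_numpy() * 1e6


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

@dataclass
class DispersionEstimate:
    """Common and per-gene (shrunk) NB dispersions."""

    common: float
    per_gene: pd.Series
    shrink_weight: float


def estimate_dispersion(
    counts: CountMatrix,
    factors: pd.Series | None = None,
    shrink_weight: float = 0.7,
    min_mean: float = 1.0,
) -> DispersionEstimate:
    """Method-of-moments dispersion, shrunk toward the common value.

    For each gene the within-group mean and variance of normalized counts
    give a raw moment estimate phi_g = (var - mu) / mu**2, pooled over the
    two groups by degrees of freedom.  The common dispersion is the mean of
    the raw estimates over genes with mean >= ``min_mean`` (raw values may
    be negative; the common value is clamped at zero only at the end, which
    keeps it nearly unbiased in the Poisson limit).  Per-gene dispersions
    are ``shrink_weight * common + (1 - shrink_weight) * raw``, clamped to
    be non-negative; constant genes get exactly zero raw dispersion.

    A group with fewer than 2 samples contributes nothing; if neither group
    has 2 samples the common estimate falls back to 0 with a warning.
    """
    if not 0 <= shrink_weight <= 1:
        raise ValueError("shrink_weight must lie in [0, 1]")
    if factors is None:
        factors = normalize(counts, "libsize")
    eff = counts.library_sizes.astype(float) * factors
    common_lib = float(np.exp(np.mean(np.log(eff))))
    scaled = counts.counts.to_numpy(dtype=float) * (common_lib / eff.to_numpy())

    raw = np.full(counts.counts.shape[0], np.nan)
    num = np.zeros(counts.counts.shape[0])
    den = np.zeros(counts.counts.shape[0])
    usable_group = False
    for group in (TUMOR, NORMAL):
        cols = np.asarray(counts.labels == group)
        n = int(cols.sum())
        if n < 2:
            continue
        usable_group = True
        sub = scaled[:, cols]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = (var - mu) / mu**2
        ok = mu > 0
        w = float(n - 1)
        num[ok] += w * phi[ok]
        den[ok] += w
    if not usable_group:
        warnings.warn(
            "no group has >= 2 samples; falling back to common dispersion 0",
            stacklevel=2,
        )
        per_gene = pd.Series(0.0, index=counts.genes)
        return DispersionEstimate(common=0.0, per_gene=per_gene,
                                  shrink_weight=shrink_weight)
    with np.errstate(invalid="ignore"):
        raw = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)

    gene_means = scaled.mean(axis=1)
    informative = (den > 0) & (gene_means >= min_mean) & np.isfinite(raw)
    common = float(max(0.0, np.mean(raw[informative]))) if informative.any() else 0.0

    raw_filled = np.where(np.isfinite(raw), raw, common)
    shrunk = np.maximum(
        0.0, shrink_weight * common + (1.0 - shrink_weight) * raw_filled
    )
    per_gene = pd.Series(shrunk, index=counts.genes, name="dispersion")
    return DispersionEstimate(common=common, per_gene=per_gene,
                              shrink_weight=shrink_weight)


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

def _group_total_logpmf(
    k: np.ndarray, n_samples: int, mu_per_sample: float, phi: float
) -> np.ndarray:
    """log P(group total = k) for a sum of ``n_samples`` iid NB draws.

    A sum of n iid NB(mu, phi) variables is NB with mean n*mu and
    dispersion phi/n (shape r = n/phi).  phi = 0 is the Poisson limit.
    """
    total_mu = n_samples * mu_per_sample
    if phi == 0.0:
        return stats.poisson.logpmf(k, total_mu)
    r = n_samples / phi
    p = r / (r + total_mu)
    return stats.nbinom.logpmf(k, r, p)


def exact_test(
    counts_a: Sequence[float] | np.ndarray,
    counts_b: Sequence[float] | np.ndarray,
    phi: float,
) -> float:
    """Two-sided NB exact test for a difference between two count groups.

    Both groups are assumed to be on a common library size already (see
    :func:`de_table`, which rescales and rounds).  Conditional on the grand
    total t, the group-A total follows the distribution proportional to
    P_A(k) * P_B(t - k); the returned p-value is the total conditional
    probability of all splits k whose probability does not exceed the
    observed one.  By construction p is in (0, 1]; two groups of all-zero
    counts give p = 1.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    if phi < 0:
        raise ValueError("dispersion must be non-negative")
    n_a, n_b = a.size, b.size
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups need at least one sample")
    s_a = int(round(a.sum()))
    s_b = int(round(b.sum()))
    t = s_a + s_b
    if t == 0:
        return 1.0

    mu = t / (n_a + n_b)
    k = np.arange(t + 1)
    log_joint = (
        _group_total_logpmf(k, n_a, mu, phi)
        + _group_total_logpmf(t - k, n_b, mu, phi)
    )
    # normalize on the log scale for numerical safety
    log_norm = special.logsumexp(log_joint)
    log_cond = log_joint - log_norm
    obs = log_cond[s_a]
    # tolerance guards against ties split by floating-point rounding
    keep = log_cond <= obs + 1e-10
    if keep.all():
        return 1.0
    p = float(np.exp(special.logsumexp(log_cond[keep])))
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# DE table and filtering
# ---------------------------------------------------------------------------

def de_table(
    counts: CountMatrix,
    factors: pd.Series | None = None,
    dispersion: DispersionEstimate | None = None,
    fc_pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene fold changes and exact-test p-values (no filtering).

    Fold change is the tumor/normal ratio of mean CPM with a pseudocount
    (default 0.5) added before division so FC is always finite and
    positive.  For the exact test each sample's counts are scaled to the
    geometric-mean effective library and rounded, giving pseudo-counts on
    a common library size.  Columns: gene, mean_cpm_tumor,
    mean_cpm_normal, FC, logFC, PValue, FDR, direction, passes_filter
    (the last two filled by :func:`call_degs` thresholds; the table
    returned here uses the default thresholds).
    """
    for group in (TUMOR, NORMAL):
        if (counts.labels == group).sum() < 1:
            raise ValueError(f"no {group} samples")
    if factors is None:
        factors = normalize(counts, "libsize")
    if dispersion is None:
        dispersion = estimate_dispersion(counts, factors)

    cpm_mat = cpm(counts, factors, pseudocount=fc_pseudocount)
    tumor_cols = counts.group_columns(TUMOR)
    normal_cols = counts.group_columns(NORMAL)
    mean_t = cpm_mat[tumor_cols].mean(axis=1)
    mean_n = cpm_mat[normal_cols].mean(axis=1)
    fc = mean_t / mean_n

    eff = counts.library_sizes.astype(float) * factors
    common_lib = float(np.exp(np.mean(np.log(eff))))
    scaled = counts.counts.to_numpy(dtype=float) * (common_lib / eff.to_numpy())
    pseudo = np.round(scaled).astype(np.int64)

    idx_t = np.asarray(counts.labels == TUMOR)
    idx_n = np.asarray(counts.labels == NORMAL)
    phis = dispersion.per_gene.to_numpy()
    pvals = np.empty(len(counts.genes))
    for i in range(len(counts.genes)):
        pvals[i] = exact_test(pseudo[i, idx_t], pseudo[i, idx_n], phis[i])

    fdr = stats.false_discovery_control(pvals, method="bh")
    table = pd.DataFrame(
        {
            "gene": counts.genes,
            "mean_cpm_tumor": mean_t.to_numpy(),
            "mean_cpm_normal": mean_n.to_numpy(),
            "FC": fc.to_numpy(),
            "logFC": np.log2(fc.to_numpy()),
            "PValue": pvals,
            "FDR": fdr,
        }
    )
    return _apply_filter(table)


def _apply_filter(
    table: pd.DataFrame,
    p_thresh: float = 0.05,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
) -> pd.DataFrame:
    passes = (table["PValue"] < p_thresh) & (
        (table["FC"] > fc_up) | (table["FC"] < fc_down)
    )
    direction = np.where(
        passes & (table["FC"] > 1.0),
        "up",
        np.where(passes, "down", "ns"),
    )
    out = table.copy()
    out["direction"] = direction
    out["passes_filter"] = passes.to_numpy()
    return out


@dataclass
class DEGCall:
    """Filtered DEG table plus up/down tallies."""

    table: pd.DataFrame
    n_up: int
    n_down: int

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])


def call_degs(
    table: pd.DataFrame,
    p_thresh: float = 0.05,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
) -> DEGCall:
    """Apply the DE filter: p < ``p_thresh`` and (FC > ``fc_up`` or
    FC < ``fc_down``), all inequalities strict.

    Returns only the passing genes, tagged up (FC > 1) or down, together
    with the up/down counts.  A gene at FC exactly 2.0 fails the default
    filter regardless of its p-value.
    """
    refreshed = _apply_filter(table, p_thresh, fc_up, fc_down)
    kept = refreshed[refreshed["passes_filter"]].reset_index(drop=True)
    n_up = int((kept["direction"] == "up").sum())
    n_down = int((kept["direction"] == "down").sum())
    return DEGCall(table=kept, n_up=n_up, n_down=n_down)


def write_deg_table(table: pd.DataFrame, path: str | Path) -> None:
    cols = ["gene", "logFC", "FC", "PValue", "FDR", "direction", "passes_filter"]
    table[cols].to_csv(path, sep="\t", index=False)
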