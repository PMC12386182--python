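"""Per-condition differential expression on raw counts.

The workflow mirrors the classic count-based testing chain: drop genes
expressed below 1 CPM in more than half of an experiment's libraries,
compute trimmed-mean-of-M-values (TMM) normalisation factors, estimate a
single common negative-binomial dispersion by conditional maximum
likelihood, and test each stress condition against its control with a
two-group NB exact test, Benjamini-Hochberg adjusted within the
condition.

Model: counts ~ NB(mean mu, variance mu + phi * mu^2).  For the exact
test, each library is deterministically scaled (and rounded) to the
geometric-mean effective library size, counts are summed within groups,
and the group sums are treated as NB with dispersion phi / n_group.  The
two-sided p-value follows the "small probabilities" rule: the sum of all
conditional outcome probabilities not exceeding that of the observed
split.  This is a documented approximation to the quantile-adjusted
conditional ML approach used by established count-model tools, not a
byte-level reimplementation of any of them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from lightmeta.config import PipelineConfig
from lightmeta.datamodel import CountStudy, SampleRecord, ValidationError

log = logging.getLogger("lightmeta")

PHI_FLOOR = 1e-6
PHI_CEIL = 10.0
_BINOMIAL_PHI = 1e-8  # below this the NB conditional is numerically Poisson/binomial


@dataclass
class DEGRecord:
    """Result of testing one gene in one stress-vs-control contrast."""

    gene_id: str
    condition_id: str
    logFC: float
    logCPM: float
    pvalue: float
    FDR: float
    direction: str  # up / down / ns


@dataclass
class Contrast:
    """One stress condition and the control libraries it is tested against."""

    condition_id: str
    stress_sample_ids: list[str]
    control_sample_ids: list[str]
    strategy: str  # time_matched / common_control

    def __post_init__(self) -> None:
        if not self.stress_sample_ids or not self.control_sample_ids:
            raise ValidationError(
                f"contrast {self.condition_id!r}: both sample sets must be non-empty"
            )
        if set(self.stress_sample_ids) & set(self.control_sample_ids):
            raise ValidationError(
                f"contrast {self.condition_id!r}: stress and control samples overlap"
            )


# ---------------------------------------------------------------------------
# filtering / normalisation
# ---------------------------------------------------------------------------

def filter_low_expression(
    counts: np.ndarray,
    sample_ids: Sequence[str] | None = None,
    cpm_min: float = 1.0,
) -> np.ndarray:
    """Boolean mask of genes retained by the low-expression filter.

    A gene is dropped iff its CPM (library-size only, no TMM factor)
    falls below ``cpm_min`` in *more than half* of the samples, i.e. in
    strictly more than floor(n/2) of them.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape[1] < 2:
        raise ValidationError("low-expression filter needs >= 2 samples")
    lib = counts.sum(axis=0)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        name = sample_ids[zero[0]] if sample_ids is not None else f"column {zero[0]}"
        raise ValidationError(f"library size of sample {name!r} is 0; CPM undefined")
    cpm_mat = counts / lib * 1e6
    n_low = (cpm_mat < cpm_min).sum(axis=1)
    return n_low <= counts.shape[1] // 2


def _trimmed_indices(values: np.ndarray, trim: float) -> np.ndarray:
    """Ranks kept after symmetric two-tail trimming of ``trim`` per tail."""
    n = values.size
    lo = int(np.floor(n * trim)) + 1
    hi = n + 1 - lo
    # average ranks keep ties symmetric, matching the usual rank() convention
    order = pd.Series(values).rank(method="average").to_numpy()
    return (order >= lo) & (order <= hi)


def tmm_factors(
    counts: np.ndarray,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    sample_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Per-sample TMM normalisation factors, geometric mean 1.

    The reference library is the one whose upper-quartile count fraction
    is closest to the mean upper-quartile fraction.  For each sample the
    factor is 2 to the weighted mean of M-values (log2 expression
    ratios), after trimming ``trim_m`` of M-values and ``trim_a`` of
    A-values from each tail; weights are inverse asymptotic binomial
    variances.  Genes with a zero count in either library of a pair are
    excluded.
    """
    counts = np.asarray(counts, dtype=float)
    n_samples = counts.shape[1]
    if n_samples < 2:
        raise ValidationError("TMM needs >= 2 samples")
    lib = counts.sum(axis=0)
    if np.any(lib == 0):
        raise ValidationError("zero library size")

    q75 = np.array([np.quantile(counts[:, j], 0.75) for j in range(n_samples)]) / lib
    ref = int(np.argmin(np.abs(q75 - q75.mean())))

    factors = np.ones(n_samples)
    y_r = counts[:, ref]
    n_r = lib[ref]
    for j in range(n_samples):
        if j == ref:
            continue
        y_k = counts[:, j]
        n_k = lib[j]
        ok = (y_k > 0) & (y_r > 0)
        if not np.any(ok):
            name = sample_ids[j] if sample_ids is not None else f"column {j}"
            log.warning("TMM: sample %r shares no expressed genes with reference; factor=1", name)
            continue
        yk, yr = y_k[ok], y_r[ok]
        m = np.log2((yk / n_k) / (yr / n_r))
        a = 0.5 * np.log2((yk / n_k) * (yr / n_r))
        w = 1.0 / ((n_k - yk) / (n_k * yk) + (n_r - yr) / (n_r * yr))
        keep = _trimmed_indices(m, trim_m) & _trimmed_indices(a, trim_a)
        if not np.any(keep):
            continue
        f = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
        if np.isfinite(f):
            factors[j] = 2.0 ** f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def cpm(
    counts: np.ndarray,
    lib_sizes: np.ndarray,
    factors: np.ndarray | None = None,
) -> np.ndarray:
    """Counts per million over effective library sizes (lib_size x factor)."""
    counts = np.asarray(counts, dtype=float)
    lib = np.asarray(lib_sizes, dtype=float)
    eff = lib * (np.ones_like(lib) if factors is None else np.asarray(factors, dtype=float))
    if np.any(eff <= 0):
        raise ValidationError("effective library sizes must be positive")
    return counts / eff * 1e6


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

def _pseudo_counts(counts: np.ndarray, eff_sizes: np.ndarray) -> tuple[np.ndarray, float]:
    """Scale every library to the geometric-mean effective size and round."""
    eff = np.asarray(eff_sizes, dtype=float)
    n_star = float(np.exp(np.mean(np.log(eff))))
    pseudo = np.rint(np.asarray(counts, dtype=float) * (n_star / eff))
    return pseudo, n_star


def _group_cond_loglik(pseudo: np.ndarray, group_sizes: Sequence[int], phi: float) -> float:
    """Summed conditional NB log-likelihood given per-gene group totals.

    For one group with counts y_1..y_n (equal library sizes) and total z:
    l(phi) = sum_i lgamma(y_i + r) - n lgamma(r) + lgamma(n r) - lgamma(z + n r),
    with r = 1/phi.  Terms constant in phi are omitted.
    """
    r = 1.0 / phi
    total = 0.0
    start = 0
    for n in group_sizes:
        if n < 2:
            start += n
            continue
        block = pseudo[:, start:start + n]
        z = block.sum(axis=1)
        total += float(
            np.sum(gammaln(block + r)) - block.size * gammaln(r)
            + z.size * gammaln(n * r) - np.sum(gammaln(z + n * r))
        )
        start += n
    return total


def estimate_common_dispersion(
    counts: np.ndarray,
    groups: Sequence[str],
    lib_sizes: np.ndarray | None = None,
    factors: np.ndarray | None = None,
) -> float:
    """Common NB dispersion phi maximising the conditional log-likelihood.

    Libraries are scaled to their geometric-mean effective size; the
    likelihood conditions on per-gene totals within each replicate
    group.  Maximised over log10(phi) on [1e-6, 10] by bounded scalar
    search.  Degenerate inputs (no replicated group with variation)
    return the floor 1e-6 with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    groups = list(groups)
    if counts.shape[1] != len(groups):
        raise ValidationError("groups must name every sample column")
    if counts.shape[1] < 2:
        raise ValidationError("dispersion estimation needs >= 2 samples")
    lib = counts.sum(axis=0) if lib_sizes is None else np.asarray(lib_sizes, dtype=float)
    eff = lib * (np.ones_like(lib) if factors is None else np.asarray(factors, dtype=float))

    # reorder columns so each group is contiguous
    order: list[int] = []
    sizes: list[int] = []
    for g in dict.fromkeys(groups):
        idx = [i for i, gg in enumerate(groups) if gg == g]
        order.extend(idx)
        sizes.append(len(idx))
    pseudo, _ = _pseudo_counts(counts[:, order], eff[order])

    # keep genes that are expressed in a replicated group; if no gene varies
    # within any group the likelihood is flat and the floor is returned
    start = 0
    informative = np.zeros(pseudo.shape[0], dtype=bool)
    varying = False
    for n in sizes:
        if n >= 2:
            block = pseudo[:, start:start + n]
            informative |= block.sum(axis=1) > 0
            varying = varying or bool(np.any(block.std(axis=1) > 0))
        start += n
    if not np.any(informative) or not varying or max(sizes) < 2:
        log.warning("estimate_common_dispersion: degenerate input, returning floor %g", PHI_FLOOR)
        return PHI_FLOOR
    pseudo = pseudo[informative]

    res = minimize_scalar(
        lambda lp: -_group_cond_loglik(pseudo, sizes, 10.0 ** lp),
        bounds=(np.log10(PHI_FLOOR), np.log10(PHI_CEIL)),
        method="bounded",
        options={"xatol": 1e-4},
    )
    return float(max(PHI_FLOOR, 10.0 ** res.x))


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

def _cond_log_pmf(s: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """Log conditional pmf of the group-B sum over k = 0..s given total s."""
    k = np.arange(s + 1)
    if phi < _BINOMIAL_PHI:
        # Poisson limit: conditional is binomial with p = n_b / (n_a + n_b)
        p = n_b / (n_a + n_b)
        logpmf = (
            gammaln(s + 1) - gammaln(k + 1) - gammaln(s - k + 1)
            + k * np.log(p) + (s - k) * np.log1p(-p)
        )
    else:
        r_a = n_a / phi
        r_b = n_b / phi
        # log NB(k; r_b) + log NB(s-k; r_a), mean terms cancel on conditioning
        logpmf = (
            gammaln(k + r_b) - gammaln(k + 1)
            + gammaln(s - k + r_a) - gammaln(s - k + 1)
        )
    return logpmf - logsumexp(logpmf)


def exact_nb_pvalue(y_a: int, y_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional NB p-value by the small-probabilities rule."""
    if phi < 0:
        raise ValidationError(f"dispersion must be >= 0, got {phi}")
    s = int(y_a + y_b)
    if s == 0:
        return 1.0
    logpmf = _cond_log_pmf(s, n_a, n_b, phi)
    obs = logpmf[int(y_b)]
    keep = logpmf <= obs + 1e-10  # tolerance so symmetric ties are counted
    return float(min(1.0, np.exp(logsumexp(logpmf[keep]))))


def nb_exact_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    lib_sizes: np.ndarray,
    factors: np.ndarray,
    phi: float,
    prior_count: float = 0.125,
    logcpm_prior: float = 2.0,
) -> pd.DataFrame:
    """Exact NB test of group B (stress) vs group A (control), per gene.

    ``lib_sizes`` and ``factors`` cover the columns of A then B, in
    order.  Returns a frame with columns ``pvalue``, ``logFC`` (B over
    A) and ``logCPM``.
    """
    if phi < 0:
        raise ValidationError(f"dispersion must be >= 0, got {phi}")
    counts_a = np.atleast_2d(np.asarray(counts_a, dtype=float))
    counts_b = np.atleast_2d(np.asarray(counts_b, dtype=float))
    n_a, n_b = counts_a.shape[1], counts_b.shape[1]
    if n_a < 1 or n_b < 1:
        raise ValidationError("both groups need >= 1 sample")
    lib = np.asarray(lib_sizes, dtype=float)
    fac = np.asarray(factors, dtype=float)
    if lib.size != n_a + n_b or fac.size != n_a + n_b:
        raise ValidationError("lib_sizes/factors must cover both groups")

    eff = lib * fac
    all_counts = np.hstack([counts_a, counts_b])
    pseudo, n_star = _pseudo_counts(all_counts, eff)
    y_a = pseudo[:, :n_a].sum(axis=1)
    y_b = pseudo[:, n_a:].sum(axis=1)

    pvals = np.ones(pseudo.shape[0])
    for i in range(pseudo.shape[0]):
        pvals[i] = exact_nb_pvalue(int(y_a[i]), int(y_b[i]), n_a, n_b, phi)

    mean_a = y_a / n_a
    mean_b = y_b / n_b
    # shrinkage prior expressed per million of the common library size, so
    # that rescaling depth leaves fold changes unchanged
    p0 = prior_count * n_star / 1e6
    logfc = np.where(
        (y_a + y_b) == 0,
        0.0,
        np.log2((mean_b + p0) / (mean_a + p0)),
    )
    mean_cpm = (all_counts / eff * 1e6).mean(axis=1)
    logcpm = np.log2(mean_cpm + logcpm_prior)
    return pd.DataFrame({"pvalue": pvals, "logFC": logfc, "logCPM": logcpm})


# ---------------------------------------------------------------------------
# multiple testing and DEG calling
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1] and contain no NaN")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    results: pd.DataFrame,
    condition_id: str,
    gene_ids: Sequence[str],
    fdr_max: float = 0.05,
    lfc_min: float = 0.5,
) -> list[DEGRecord]:
    """Attach FDR and up/down/ns direction labels (inclusive thresholds)."""
    fdr = bh_adjust(results["pvalue"].to_numpy())
    out = []
    for i, gene in enumerate(gene_ids):
        lfc = float(results["logFC"].iloc[i])
        significant = fdr[i] <= fdr_max
        if significant and lfc >= lfc_min:
            direction = "up"
        elif significant and lfc <= -lfc_min:
            direction = "down"
        else:
            direction = "ns"
        out.append(
            DEGRecord(
                gene_id=gene,
                condition_id=condition_id,
                logFC=lfc,
                logCPM=float(results["logCPM"].iloc[i]),
                pvalue=float(results["pvalue"].iloc[i]),
                FDR=float(fdr[i]),
                direction=direction,
            )
        )
    return out


# ---------------------------------------------------------------------------
# contrast construction and per-experiment driver
# ---------------------------------------------------------------------------

def build_contrasts(samples: Sequence[SampleRecord]) -> list[Contrast]:
    """One contrast per stress condition of a single experiment.

    When the experiment provides controls at multiple matched durations,
    each stress condition is tested against the control sharing its
    duration (time-matched strategy); otherwise every stress condition
    is tested against the pooled common control.  A stress condition
    without a matching timed control falls back to the common control
    with a warning.
    """
    controls = [s for s in samples if s.is_control]
    if not controls:
        raise ValidationError("experiment has no control samples")
    control_durations = sorted({s.duration_min for s in controls})
    time_matched = len(control_durations) > 1

    stress_conditions: dict[str, list[SampleRecord]] = {}
    for s in samples:
        if not s.is_control:
            stress_conditions.setdefault(s.condition_id, []).append(s)

    out = []
    all_control_ids = [s.sample_id for s in controls]
    for cond, members in stress_conditions.items():
        if time_matched:
            dur = members[0].duration_min
            matched = [s.sample_id for s in controls if s.duration_min == dur]
            if matched:
                out.append(Contrast(cond, [m.sample_id for m in members], matched, "time_matched"))
                continue
            log.warning(
                "contrast %r: no control at duration %.6g min; using common control",
                cond, dur,
            )
        out.append(Contrast(cond, [m.sample_id for m in members], all_control_ids, "common_control"))
    return out


def run_experiment_de(
    study: CountStudy,
    config: PipelineConfig | None = None,
) -> tuple[list[DEGRecord], dict]:
    """Full DE workflow for the samples of one experiment.

    Returns all per-(gene, condition) records (including ``ns``) plus a
    small info dict (retained gene mask, factors, dispersion).
    """
    cfg = config or PipelineConfig()
    sample_ids = study.sample_ids
    mask = filter_low_expression(study.counts, sample_ids, cfg.cpm_filter)
    genes = [g for g, m in zip(study.genes, mask) if m]
    counts = study.counts[mask, :].astype(float)
    lib = study.counts.sum(axis=0).astype(float)  # library sizes from all genes
    factors = tmm_factors(counts, sample_ids=sample_ids)
    phi = estimate_common_dispersion(
        counts, [s.condition_id for s in study.samples], lib, factors
    )

    idx = {sid: j for j, sid in enumerate(sample_ids)}
    records: list[DEGRecord] = []
    for contrast in build_contrasts(study.samples):
        a = [idx[s] for s in contrast.control_sample_ids]
        b = [idx[s] for s in contrast.stress_sample_ids]
        cols = a + b
        res = nb_exact_test(
            counts[:, a], counts[:, b], lib[cols], factors[cols], phi,
            prior_count=cfg.logfc_prior_scale, logcpm_prior=cfg.logcpm_prior,
        )
        records.extend(
            call_degs(res, contrast.condition_id, genes, cfg.fdr_max, cfg.lfc_min)
        )
    info = {"retained_mask": mask, "factors": factors, "dispersion": phi, "genes": genes}
    return records, info


def deg_records_frame(records: Sequence[DEGRecord]) -> pd.DataFrame:
    cols = ["condition_id", "gene_id", "logFC", "logCPM", "pvalue", "FDR", "direction"]
    if not records:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([vars(r) for r in records])[cols]
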