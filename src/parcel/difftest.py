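"""Per-position differential V1-count testing and the position score transform.

One ligand condition is compared against the pool of all other conditions
at every transcript position.  Counts are modeled as negative binomial
with a single common dispersion shared across positions (variance
``mu + phi * mu**2``); significance comes from an exact test conditional
on the per-position total, the count analogue of Fisher's exact test.

Positions that pass the abundance threshold (average normalized counts
per sample ``a > 1`` by default) receive a score

    ``s_i = ln(0.1) - ln(pval_i)``

which is positive exactly when ``pval_i < 0.1``; positions failing the
abundance threshold receive a flat penalty score (default -10).  The
score track feeds the maximal-segment search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import binom

from .counts import CountMatrix, SampleDesign

__all__ = [
    "ScoreTrack",
    "tmm_norm_factors",
    "effective_library_sizes",
    "estimate_common_dispersion",
    "nb_exact_test",
    "test_all_positions",
    "score_positions",
    "LN_PVAL_REF",
]

LN_PVAL_REF = float(np.log(0.1))  # score zero-point: s_i = ln(0.1) - ln(pval_i)
_TINY_P = float(np.nextafter(0.0, 1.0))


@dataclass
class ScoreTrack:
    """Ordered per-position scores for one transcript.

    ``tested[i]`` is True where the position passed the abundance
    threshold and carries a p-value-derived score; False marks penalized
    positions (flat penalty score).
    """

    transcript: str
    scores: np.ndarray
    tested: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.tested = np.asarray(self.tested, dtype=bool)
        if self.scores.shape != self.tested.shape:
            raise ValueError("scores and tested must have identical shape")


# ---------------------------------------------------------------------------
# normalization


def tmm_norm_factors(
    cm: CountMatrix,
    *,
    log_ratio_trim: float = 0.3,
    abs_expr_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors (geometric mean 1).

    Positions act as tags; the reference sample is the one whose
    upper-quartile count fraction is closest to the mean upper quartile.
    Falls back to unit factors when the data are too sparse to trim.
    """
    y = np.vstack([arr for arr in cm.counts.values()]) if cm.counts else np.zeros((0, len(cm.samples)))
    lib = y.sum(axis=0).astype(float)
    factors = np.ones(len(cm.samples))
    if y.size == 0 or np.any(lib == 0):
        return pd.Series(factors, index=cm.samples, name="norm_factor")

    expressed = y[y.any(axis=1)]
    uq = np.percentile(expressed / lib, 75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    for j in range(len(cm.samples)):
        if j == ref:
            continue
        keep = (expressed[:, j] > 0) & (expressed[:, ref] > 0)
        if keep.sum() < 10:
            continue
        yj, yr = expressed[keep, j], expressed[keep, ref]
        m = np.log2((yj / lib[j]) / (yr / lib[ref]))
        a = 0.5 * np.log2((yj / lib[j]) * (yr / lib[ref]))
        w = (lib[j] - yj) / (lib[j] * yj) + (lib[ref] - yr) / (lib[ref] * yr)
        lo_m, hi_m = np.quantile(m, [log_ratio_trim, 1 - log_ratio_trim])
        lo_a, hi_a = np.quantile(a, [abs_expr_trim, 1 - abs_expr_trim])
        keep2 = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if keep2.sum() == 0 or not np.isfinite(m[keep2]).all():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            wk = 1.0 / w[keep2]
        factors[j] = 2 ** (np.sum(wk * m[keep2]) / np.sum(wk))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.samples, name="norm_factor")


def effective_library_sizes(cm: CountMatrix, normalization: str = "tmm") -> pd.Series:
    """Library sizes times TMM factors ('tmm') or raw sizes ('library')."""
    lib = cm.library_size.astype(float)
    if normalization == "tmm":
        lib = lib * tmm_norm_factors(cm)
    elif normalization != "library":
        raise ValueError(f"unknown normalization {normalization!r}")
    return lib.rename("effective_library_size")


def _normalized_counts(cm: CountMatrix, eff_lib: pd.Series) -> dict[str, np.ndarray]:
    lib = eff_lib.to_numpy(dtype=float)
    if np.any(lib <= 0):
        scale = np.ones_like(lib)
    else:
        scale = np.exp(np.mean(np.log(lib))) / lib
    return {t: arr * scale for t, arr in cm.counts.items()}


# ---------------------------------------------------------------------------
# dispersion


def _group_conditional_loglik(y: np.ndarray, phi: float) -> float:
    """Conditional NB log-likelihood of within-group counts given row sums.

    ``y`` is (positions, replicates) of library-size-equalized integer
    counts.  Conditioning on the per-position total removes the unknown
    mean, leaving a likelihood in the dispersion alone (qCML).
    """
    n = y.shape[1]
    r = 1.0 / phi
    z = y.sum(axis=1)
    ll = (
        gammaln(y + r).sum(axis=1)
        - n * gammaln(r)
        - gammaln(z + n * r)
        + gammaln(n * r)
    )
    # y! terms are phi-free but keep the value a proper log-probability
    ll += gammaln(z + 1) - gammaln(y + 1).sum(axis=1)
    return float(ll.sum())


def estimate_common_dispersion(
    cm: CountMatrix,
    design: SampleDesign,
    *,
    normalization: str = "tmm",
    max_dispersion: float = 20.0,
) -> float:
    """Common NB dispersion by conditional maximum likelihood (qCML-style).

    Counts are scaled to a common effective library size and rounded
    (pseudo-counts); the conditional likelihood given per-position group
    totals is then maximized over a single dispersion shared by all
    positions and all replicated condition groups.  Returns 0 when the
    optimum sits at the Poisson boundary.
    """
    design.validate_against(cm)
    groups = [
        [cm.sample_index(s) for s in design.samples_for(c)]
        for c in design.conditions
        if len(design.samples_for(c)) >= 2
    ]
    if not groups:
        raise ValueError(
            "no condition has >= 2 replicates; dispersion cannot be estimated "
            "- supply a dispersion value explicitly"
        )
    eff = effective_library_sizes(cm, normalization)
    norm = _normalized_counts(cm, eff)
    stacked = np.vstack([arr for arr in norm.values()])
    pseudo = np.rint(stacked).astype(np.int64)

    blocks = []
    for idx in groups:
        y = pseudo[:, idx]
        y = y[y.sum(axis=1) > 0]
        if len(y):
            blocks.append(y)
    if not blocks:
        return 0.0

    def neg_ll(u: float) -> float:
        phi = float(np.exp(u))
        return -sum(_group_conditional_loglik(y, phi) for y in blocks)

    lo, hi = np.log(1e-8), np.log(max_dispersion)
    res = minimize_scalar(neg_ll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    phi = float(np.exp(res.x))
    if phi <= 2e-8 or neg_ll(lo) <= res.fun:
        return 0.0
    return phi


# ---------------------------------------------------------------------------
# exact test


def _nb_logpmf(y: np.ndarray, mean: float, size: float) -> np.ndarray:
    return (
        gammaln(y + size)
        - gammaln(size)
        - gammaln(y + 1)
        + size * np.log(size / (size + mean))
        + y * np.log(mean / (size + mean))
    )


def _conditional_pmf(t: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """P(sum_A = y | sum_A + sum_B = t) for y = 0..t under common-mean NB."""
    y = np.arange(t + 1)
    if phi <= 0:
        return binom.pmf(y, t, n_a / (n_a + n_b))
    mu = t / (n_a + n_b)  # per-replicate mean under the null
    if mu == 0:
        out = np.zeros(t + 1)
        out[0] = 1.0
        return out
    la = _nb_logpmf(y, n_a * mu, n_a / phi)
    lb = _nb_logpmf(y[::-1], n_b * mu, n_b / phi)
    log_joint = la + lb
    log_joint -= log_joint.max()
    pmf = np.exp(log_joint)
    return pmf / pmf.sum()


def nb_exact_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    dispersion: float,
    lib_sizes: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Two-sided NB exact test for one position (doubled-tail convention).

    Group sums are compared under their conditional distribution given
    the total; the p-value doubles the smaller inclusive tail and is
    capped at 1.  With ``dispersion = 0`` and equal library sizes this is
    the two-sided binomial exact test on the split of the total.  A total
    of zero returns 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be non-negative")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if lib_sizes is not None:
        la, lb = (np.asarray(x, dtype=float) for x in lib_sizes)
        ref = np.exp(np.mean(np.log(np.concatenate([la, lb]))))
        a = a * (ref / la)
        b = b * (ref / lb)
    sa = int(np.rint(a.sum()))
    sb = int(np.rint(b.sum()))
    t = sa + sb
    if t == 0:
        return 1.0
    pmf = _conditional_pmf(t, len(a), len(b), dispersion)
    lower = float(pmf[: sa + 1].sum())
    upper = float(pmf[sa:].sum())
    return min(1.0, 2.0 * min(lower, upper))


# ---------------------------------------------------------------------------
# per-position testing and scoring


def test_all_positions(
    cm: CountMatrix,
    design: SampleDesign,
    contrast: str,
    *,
    a_threshold: float = 1.0,
    dispersion: float | None = None,
    normalization: str = "tmm",
    pseudo_count: float = 0.5,
) -> pd.DataFrame:
    """Differential test of every abundance-passing position.

    Returns one row per position of every transcript with columns
    ``transcript, position, a_mean, abundance_pass, pval, log2fc``.
    ``a_mean`` is the average normalized count per sample;
    positions with ``a_mean <= a_threshold`` keep NaN p-values.
    ``log2fc`` is contrast over rest, with a pseudo-count guard on the
    group means.
    """
    design.validate_against(cm)
    a_samples, b_samples = design.contrast_groups(contrast)
    if not b_samples:
        raise ValueError("contrast covers every sample; nothing to compare against")
    if dispersion is None:
        dispersion = estimate_common_dispersion(cm, design, normalization=normalization)

    eff = effective_library_sizes(cm, normalization)
    norm = _normalized_counts(cm, eff)
    ia = [cm.sample_index(s) for s in a_samples]
    ib = [cm.sample_index(s) for s in b_samples]

    frames = []
    for t, arr in norm.items():
        a_mean = arr.mean(axis=1)
        passed = a_mean > a_threshold
        mean_a = arr[:, ia].mean(axis=1)
        mean_b = arr[:, ib].mean(axis=1)
        log2fc = np.log2((mean_a + pseudo_count) / (mean_b + pseudo_count))
        pseudo = np.rint(arr).astype(np.int64)
        pvals = np.full(arr.shape[0], np.nan)
        for i in np.flatnonzero(passed):
            pvals[i] = nb_exact_test(pseudo[i, ia], pseudo[i, ib], dispersion)
        frames.append(
            pd.DataFrame(
                {
                    "transcript": t,
                    "position": np.arange(1, arr.shape[0] + 1),
                    "a_mean": a_mean,
                    "abundance_pass": passed,
                    "pval": pvals,
                    "log2fc": log2fc,
                }
            )
        )
    cols = ["transcript", "position", "a_mean", "abundance_pass", "pval", "log2fc"]
    if not frames:
        return pd.DataFrame(columns=cols)
    out = pd.concat(frames, ignore_index=True)
    out.attrs["dispersion"] = dispersion
    out.attrs["contrast"] = contrast
    return out


def score_positions(
    stats: pd.DataFrame,
    *,
    penalty: float = -10.0,
    transcript_lengths: dict[str, int] | None = None,
) -> dict[str, ScoreTrack]:
    """Turn per-position p-values into score tracks.

    Tested positions get ``s_i = ln(0.1) - ln(pval_i)``; abundance-failing
    positions (and positions absent from ``stats``) get the flat penalty.
    Zero p-values are clamped to the smallest positive float with a
    warning.
    """
    tracks: dict[str, ScoreTrack] = {}
    lengths = dict(transcript_lengths or {})
    for t, grp in stats.groupby("transcript", sort=False):
        n = int(lengths.get(t, grp["position"].max()))
        scores = np.full(n, penalty, dtype=float)
        tested = np.zeros(n, dtype=bool)
        ok = grp["abundance_pass"] & grp["pval"].notna()
        pos = grp.loc[ok, "position"].to_numpy(dtype=int) - 1
        pv = grp.loc[ok, "pval"].to_numpy(dtype=float)
        if np.any(pv <= 0):
            warnings.warn("p-values of 0 clamped to smallest positive float")
            pv = np.clip(pv, _TINY_P, None)
        scores[pos] = LN_PVAL_REF - np.log(pv)
        tested[pos] = True
        tracks[t] = ScoreTrack(transcript=str(t), scores=scores, tested=tested)
    return tracks
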