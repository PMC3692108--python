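"""Monte Carlo rejection of simulated sequences by feature-space fidelity.

Candidate sequences are projected into feature space and kept only if they
look like the original set there: a per-feature two-sided quantile rule
removes 1-D outliers, and a multivariate Mahalanobis rule (chi-square
threshold against the original mean/covariance) removes candidates that
break the between-feature association structure.  The driver loop keeps
generating batches until the requested number of accepted sequences is
reached or the round budget is exhausted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .featex import FeatureSpec, extract_features
from .profilehmm import ProfileHMM, sample_from_profile
from .seqio import FeatureMatrix, SequenceSet
from .seqsim import BlueprintModel, simulate_sequences

logger = logging.getLogger(__name__)


@dataclass
class RejectionCriteria:
    """Two-sided tail mass per feature and Mahalanobis tail probability.

    ``quantile_q`` is the tail mass cut on each side of every feature
    (0 disables the 1-D rule); ``mahalanobis_alpha`` is the chi-square upper
    tail probability (candidates with d^2 above the 1-alpha quantile are
    rejected).  ``subset`` optionally restricts the multivariate rule to
    named features; ``covariance`` chooses the plain sample estimate or a
    simple robust (median/MAD-scaled) variant.
    """

    quantile_q: float = 0.025
    mahalanobis_alpha: float = 0.025
    covariance: str = "sample"
    subset: list[str] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.quantile_q < 0.5:
            raise ValueError("quantile_q must be in [0, 0.5)")
        if not 0.0 < self.mahalanobis_alpha < 1.0:
            raise ValueError("mahalanobis_alpha must be in (0, 1)")
        if self.covariance not in ("sample", "robust"):
            raise ValueError("covariance must be 'sample' or 'robust'")


@dataclass
class RejectionReport:
    n_generated: int = 0
    n_accepted: int = 0
    n_rejected_quantile: int = 0
    n_rejected_mahalanobis: int = 0
    iterations: int = 0
    shortfall: bool = False

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_generated if self.n_generated else 0.0

    def merge(self, other: "RejectionReport") -> None:
        self.n_generated += other.n_generated
        self.n_accepted += other.n_accepted
        self.n_rejected_quantile += other.n_rejected_quantile
        self.n_rejected_mahalanobis += other.n_rejected_mahalanobis
        self.iterations += other.iterations

    def to_dict(self) -> dict:
        return {
            "n_generated": self.n_generated,
            "n_accepted": self.n_accepted,
            "n_rejected_quantile": self.n_rejected_quantile,
            "n_rejected_mahalanobis": self.n_rejected_mahalanobis,
            "acceptance_rate": self.acceptance_rate,
            "iterations": self.iterations,
            "shortfall": self.shortfall,
        }


def quantile_bounds(original: FeatureMatrix, q: float) -> np.ndarray:
    """Per-feature [low, high] empirical quantile bounds (linear interpolation)."""
    if not 0.0 <= q < 0.5:
        raise ValueError("q must be in [0, 0.5)")
    if original.n < 5:
        raise ValueError("need at least 5 rows for quantile bounds")
    lo = np.quantile(original.values, q, axis=0, method="linear")
    hi = np.quantile(original.values, 1.0 - q, axis=0, method="linear")
    return np.column_stack([lo, hi])


def mahalanobis_d2(x, mean, cov) -> float:
    """Squared Mahalanobis distance (x-mean)' cov^-1 (x-mean)."""
    x = np.asarray(x, dtype=float)
    mean = np.asarray(mean, dtype=float)
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    if x.shape != mean.shape or cov.shape != (x.size, x.size):
        raise ValueError("dimension mismatch")
    diff = x - mean
    try:
        sol = np.linalg.solve(cov, diff)
    except np.linalg.LinAlgError:
        logger.warning("singular covariance: using pseudo-inverse")
        sol = np.linalg.pinv(cov) @ diff
    return float(diff @ sol)


def _location_scatter(values: np.ndarray, kind: str) -> tuple[np.ndarray, np.ndarray]:
    if kind == "robust":
        med = np.median(values, axis=0)
        mad = stats.median_abs_deviation(values, axis=0, scale="normal")
        mad = np.where(mad > 0, mad, values.std(axis=0, ddof=1))
        standardized = (values - med) / mad
        corr = np.corrcoef(standardized, rowvar=False)
        cov = corr * np.outer(mad, mad)
        return med, np.atleast_2d(cov)
    return values.mean(axis=0), np.atleast_2d(np.cov(values, rowvar=False))


def filter_candidates(candidates: FeatureMatrix, original: FeatureMatrix,
                      criteria: RejectionCriteria
                      ) -> tuple[np.ndarray, RejectionReport]:
    """Accept mask over candidate rows plus a count-conserving report.

    A candidate is rejected if any feature falls outside its quantile bounds,
    or (having passed that) if its squared Mahalanobis distance to the
    original mean exceeds the chi-square 1-alpha quantile with df equal to
    the size of the multivariate feature subset.
    """
    if candidates.feature_names != original.feature_names:
        raise ValueError("feature name mismatch between candidates and original")
    report = RejectionReport(n_generated=candidates.n, iterations=1)
    mask = np.ones(candidates.n, dtype=bool)

    if criteria.quantile_q > 0:
        bounds = quantile_bounds(original, criteria.quantile_q)
        inside = np.all(
            (candidates.values >= bounds[:, 0]) &
            (candidates.values <= bounds[:, 1]), axis=1)
        report.n_rejected_quantile = int((~inside).sum())
        mask &= inside

    subset = criteria.subset or list(original.feature_names)
    idx = [original.feature_names.index(s) for s in subset]
    if len(idx) >= 2:
        mean, cov = _location_scatter(original.values[:, idx], criteria.covariance)
        threshold = stats.chi2.ppf(1.0 - criteria.mahalanobis_alpha, df=len(idx))
        diff = candidates.values[:, idx] - mean
        try:
            sol = np.linalg.solve(cov, diff.T)
        except np.linalg.LinAlgError:
            logger.warning("singular covariance: using pseudo-inverse")
            sol = np.linalg.pinv(cov) @ diff.T
        d2 = np.einsum("ij,ji->i", diff, sol)
        far = d2 > threshold
        report.n_rejected_mahalanobis = int((far & mask).sum())
        mask &= ~far
    report.n_accepted = int(mask.sum())
    return mask, report


def simulate_sequences_with_features(
        seq_model: BlueprintModel | ProfileHMM,
        feature_spec: FeatureSpec,
        original_seqs: SequenceSet,
        criteria: RejectionCriteria,
        target_n: int,
        rng: np.random.Generator,
        max_rounds: int = 50,
        batch_size: int | None = None,
) -> tuple[SequenceSet, FeatureMatrix, RejectionReport]:
    """Sequence-driven simulation loop: generate, project, filter, accumulate.

    Returns the accepted sequences, their features and the cumulative
    rejection report; if the target is unmet after ``max_rounds`` the partial
    set is returned with ``report.shortfall`` set.
    """
    if target_n < 1:
        raise ValueError("target_n must be >= 1")
    original_features = extract_features(original_seqs, feature_spec)
    batch = batch_size or max(target_n, 1000)

    accepted_records = []
    accepted_rows = []
    total = RejectionReport()
    for round_no in range(1, max_rounds + 1):
        if isinstance(seq_model, ProfileHMM):
            cand_seqs = sample_from_profile(seq_model, batch, rng,
                                            run_tag=f"r{round_no}")
        else:
            cand_seqs = simulate_sequences(seq_model, batch, rng,
                                           run_tag=f"r{round_no}")
        cand_feats = extract_features(cand_seqs, feature_spec)
        mask, report = filter_candidates(cand_feats, original_features, criteria)
        total.merge(report)
        for i in np.flatnonzero(mask):
            accepted_records.append(cand_seqs.records[i])
            accepted_rows.append(cand_feats.values[i])
            if len(accepted_records) >= target_n:
                break
        logger.info("round %d: %d/%d accepted (cumulative %d/%d)", round_no,
                    report.n_accepted, batch, len(accepted_records), target_n)
        if len(accepted_records) >= target_n:
            break
    if not accepted_records:
        raise RuntimeError(
            f"zero acceptance over {max_rounds} rounds: criteria too tight "
            f"(q={criteria.quantile_q}, alpha={criteria.mahalanobis_alpha})")
    if len(accepted_records) < target_n:
        total.shortfall = True
        logger.warning("shortfall: %d of %d accepted after %d rounds",
                       len(accepted_records), target_n, total.iterations)

    for i, rec in enumerate(accepted_records):
        rec.identifier = f"acc_{i + 1:06d}"
    seqs = SequenceSet(accepted_records, original_seqs.alphabet)
    feats = FeatureMatrix([r.identifier for r in accepted_records],
                          list(original_features.feature_names),
                          np.array(accepted_rows))
    return seqs, feats, total
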