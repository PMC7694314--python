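"""Random-effects meta-analysis with leave-studies-out sensitivity checks.

Pooling uses inverse-variance weights. The random-effects model estimates the
between-study variance tau^2 with the DerSimonian-Laird moment estimator:

    Q    = sum w_i (md_i - md_fixed)^2,          w_i = 1 / se_i^2
    tau2 = max(0, (Q - (k - 1)) / (sum w - sum w^2 / sum w))

and re-weights studies by 1 / (se_i^2 + tau2). Confidence intervals and
p-values are normal (z) based. The sensitivity check re-pools after removing
a chosen set of studies (e.g., those a screening workflow would have missed)
and flags whether the pooled estimate's statistical significance (the 95% CI
crossing zero) or direction changed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.stats


class MetaAnalysisError(ValueError):
    """Invalid meta-analysis input."""


@dataclass(frozen=True)
class MetaStudy:
    """One study's mean difference and standard error."""

    study_id: str
    md: float
    se: float
    analysis_id: str = "primary"

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise MetaAnalysisError(f"study {self.study_id!r}: se must be > 0")


@dataclass(frozen=True)
class PooledEffect:
    """Pooled mean difference with CI, z test and heterogeneity statistics."""

    md: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    tau2: float
    q: float
    k: int
    model: str

    @property
    def significant(self) -> bool:
        """True when the CI excludes zero."""
        return self.ci_low > 0 or self.ci_high < 0


def pool(
    studies: Sequence[MetaStudy], model: str = "random", *, alpha: float = 0.05
) -> PooledEffect:
    """Inverse-variance pooled effect under a fixed or DL random-effects model."""
    if model not in ("fixed", "random"):
        raise MetaAnalysisError(f"model must be fixed/random, got {model!r}")
    k = len(studies)
    if k == 0:
        raise MetaAnalysisError("cannot pool zero studies")
    md = np.array([s.md for s in studies])
    se = np.array([s.se for s in studies])
    w = 1.0 / se**2
    md_fixed = float(np.sum(w * md) / np.sum(w))
    q = float(np.sum(w * (md - md_fixed) ** 2))

    tau2 = 0.0
    if model == "random" and k > 1:
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        if denom > 0:
            tau2 = max(0.0, (q - (k - 1)) / float(denom))

    w_star = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w_star * md) / np.sum(w_star))
    pooled_se = float(1.0 / np.sqrt(np.sum(w_star)))
    crit = float(scipy.stats.norm.ppf(1 - alpha / 2))
    z = pooled / pooled_se
    p = float(2 * scipy.stats.norm.sf(abs(z)))
    return PooledEffect(
        md=pooled,
        se=pooled_se,
        ci_low=pooled - crit * pooled_se,
        ci_high=pooled + crit * pooled_se,
        z=float(z),
        p=p,
        tau2=float(tau2),
        q=q,
        k=k,
        model=model,
    )


@dataclass(frozen=True)
class LeaveOutComparison:
    """Pooled results before/after removing studies, with change flags.

    ``defined`` is False when the removal empties the analysis; the after
    result and flags are then None rather than silently zero.
    """

    analysis_id: str
    removed_ids: frozenset[str]
    before: PooledEffect
    after: PooledEffect | None
    significance_changed: bool | None
    direction_changed: bool | None

    @property
    def defined(self) -> bool:
        return self.after is not None


def leave_out_compare(
    studies: Sequence[MetaStudy],
    removed_ids: Iterable[str],
    model: str = "random",
    *,
    alpha: float = 0.05,
) -> LeaveOutComparison:
    """Compare the pooled effect with and without the removed studies."""
    removed = frozenset(removed_ids)
    ids = {s.study_id for s in studies}
    unknown = removed - ids
    if unknown:
        raise MetaAnalysisError(f"removed ids not in the analysis: {sorted(unknown)}")
    analysis_ids = {s.analysis_id for s in studies}
    if len(analysis_ids) != 1:
        raise MetaAnalysisError(
            "studies span multiple analyses; compare per analysis_id "
            f"(got {sorted(analysis_ids)})"
        )
    before = pool(studies, model, alpha=alpha)
    remaining = [s for s in studies if s.study_id not in removed]
    if not remaining:
        return LeaveOutComparison(
            analysis_id=next(iter(analysis_ids)),
            removed_ids=removed,
            before=before,
            after=None,
            significance_changed=None,
            direction_changed=None,
        )
    after = pool(remaining, model, alpha=alpha)
    return LeaveOutComparison(
        analysis_id=next(iter(analysis_ids)),
        removed_ids=removed,
        before=before,
        after=after,
        significance_changed=before.significant != after.significant,
        direction_changed=(before.md > 0) != (after.md > 0)
        and before.md != 0
        and after.md != 0,
    )


def compare_analyses(
    studies: Sequence[MetaStudy],
    removed_ids: Iterable[str],
    model: str = "random",
    *,
    alpha: float = 0.05,
) -> list[LeaveOutComparison]:
    """Leave-out comparison for every analysis_id present in the study set."""
    removed = frozenset(removed_ids)
    out: list[LeaveOutComparison] = []
    for aid in sorted({s.analysis_id for s in studies}):
        subset = [s for s in studies if s.analysis_id == aid]
        subset_ids = {s.study_id for s in subset}
        out.append(
            leave_out_compare(subset, removed & subset_ids, model, alpha=alpha)
        )
    return out


@dataclass(frozen=True)
class RecoveryReport:
    """Bias of the pooled estimate and tau^2 over seeded replicates."""

    n_replicates: int
    mean_md: float
    bias_md: float
    mc_se_md: float
    mean_tau2: float
    bias_tau2: float
    rejection_rate: float  # share of replicates with p < 0.05


def recover_parameters(
    spec, n_replicates: int = 200, seed: int = 0, model: str = "random"
) -> RecoveryReport:
    """Generate-pool-measure loop validating the estimator on synthetic sets."""
    from dataclasses import replace

    from screensim.synthetic import generate_meta_study_set

    rng = np.random.default_rng(seed)
    mds, tau2s, rejections = [], [], 0
    for _ in range(n_replicates):
        rep_spec = replace(spec, seed=int(rng.integers(0, 2**31 - 1)))
        pooled = pool(generate_meta_study_set(rep_spec), model)
        mds.append(pooled.md)
        tau2s.append(pooled.tau2)
        rejections += pooled.p < 0.05
    mds_arr = np.asarray(mds)
    tau2_arr = np.asarray(tau2s)
    return RecoveryReport(
        n_replicates=n_replicates,
        mean_md=float(mds_arr.mean()),
        bias_md=float(mds_arr.mean() - spec.true_md),
        mc_se_md=float(mds_arr.std(ddof=1) / np.sqrt(n_replicates)),
        mean_tau2=float(tau2_arr.mean()),
        bias_tau2=float(tau2_arr.mean() - spec.tau2),
        rejection_rate=float(rejections / n_replicates),
    )
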