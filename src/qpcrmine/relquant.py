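"""Relative quantification by the comparative-Ct (2^−ΔΔCt) method.

The chain is the classic Livak pipeline:

1. ΔCt  = Ct(target) − Ct(reference), paired within one sample, which
   cancels per-sample template-loading differences;
2. ΔΔCt = ΔCt − mean ΔCt of the control treatment for the same
   (target, reference) pair, putting every sample on a log2 scale relative
   to control;
3. fold = base^(−ΔΔCt) with base 2 under the perfect-doubling assumption.

With two or more internal-control genes, the pipeline is run once per
reference and the per-replicate fold profiles are averaged
(:func:`combine_reference_profiles`), with the cross-reference Pearson
correlation of treatment-mean profiles reported as a stability diagnostic.
:func:`summarize_expression` turns per-replicate folds into per-treatment
mean ± SE rows, pinning the control row to 1 ± 0 by default (the raw
control replicates scatter around 1 with geometric mean exactly 1).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ctio import ROLE_REFERENCE, ROLE_TARGET, CtWell, DesignSpec
from .errors import AlignmentError, ConfigError, DesignError


@dataclass(frozen=True)
class DeltaCtRecord:
    """ΔCt for one sample and one (target, reference) gene pair."""

    sample_id: str
    treatment: tuple[str, ...]
    replicate: int
    target_gene: str
    reference_gene: str
    delta_ct: float


@dataclass(frozen=True)
class DeltaDeltaCtRecord:
    """ΔΔCt: one sample's ΔCt minus the control-treatment mean ΔCt."""

    sample_id: str
    treatment: tuple[str, ...]
    replicate: int
    target_gene: str
    reference_gene: str
    ddct: float


@dataclass(frozen=True)
class ExpressionEstimate:
    """Per-(treatment, gene) relative expression: mean fold, SE and n.

    ``scale`` is ``"fold"`` (2^−ΔΔCt units) or ``"log2"`` (ΔΔCt sign-flipped
    units with symmetric errors).  ``per_reference`` optionally carries the
    (mean, se) each internal-control gene would give on its own.
    """

    treatment: tuple[str, ...]
    target_gene: str
    fold_mean: float
    fold_se: float
    n: int
    scale: str = "fold"
    per_reference: Mapping[str, tuple[float, float]] | None = None


def delta_ct(
    wells: Iterable[CtWell], reference_gene: str
) -> tuple[list[DeltaCtRecord], list[CtWell]]:
    """Pair each target well with its sample's reference well.

    Returns ``(records, excluded)`` where ``excluded`` lists target wells
    dropped because either their own Ct or the sample's reference Ct is
    missing.  Raises if the reference gene never appears, or if some
    (treatment, target) group ends up with zero usable pairs.
    """
    wells = list(wells)
    ref_ct: dict[str, float | None] = {}
    saw_reference = False
    for w in wells:
        if w.gene_id == reference_gene:
            if w.role != ROLE_REFERENCE:
                raise ConfigError(
                    f"gene {reference_gene!r} is present but not marked as a reference"
                )
            saw_reference = True
            ref_ct[w.sample_id] = w.ct
    if not saw_reference:
        raise ConfigError(f"reference gene {reference_gene!r} absent from the Ct table")

    records: list[DeltaCtRecord] = []
    excluded: list[CtWell] = []
    groups_seen: set[tuple[tuple[str, ...], str]] = set()
    groups_usable: set[tuple[tuple[str, ...], str]] = set()
    for w in wells:
        if w.role != ROLE_TARGET:
            continue
        group = (w.treatment, w.gene_id)
        groups_seen.add(group)
        r = ref_ct.get(w.sample_id)
        if w.ct is None or r is None:
            excluded.append(w)
            continue
        groups_usable.add(group)
        records.append(
            DeltaCtRecord(
                sample_id=w.sample_id,
                treatment=w.treatment,
                replicate=w.replicate,
                target_gene=w.gene_id,
                reference_gene=reference_gene,
                delta_ct=w.ct - r,
            )
        )
    empty = sorted(groups_seen - groups_usable)
    if empty:
        raise DesignError(
            f"zero usable Ct pairs for (treatment, target) group(s): {empty}"
        )
    return records, excluded


def delta_delta_ct(
    records: Iterable[DeltaCtRecord], control: Sequence[str]
) -> list[DeltaDeltaCtRecord]:
    """Subtract the control-treatment mean ΔCt, per (target, reference) pair."""
    records = list(records)
    control = tuple(str(v) for v in control)
    control_means: dict[tuple[str, str], float] = {}
    for (target, ref), group in _group_by(records, lambda r: (r.target_gene, r.reference_gene)):
        ctrl = [r.delta_ct for r in group if r.treatment == control]
        if not ctrl:
            raise DesignError(
                f"control treatment {control} has no ΔCt records for "
                f"(target={target!r}, reference={ref!r})"
            )
        control_means[(target, ref)] = float(np.mean(ctrl))
    return [
        DeltaDeltaCtRecord(
            sample_id=r.sample_id,
            treatment=r.treatment,
            replicate=r.replicate,
            target_gene=r.target_gene,
            reference_gene=r.reference_gene,
            ddct=r.delta_ct - control_means[(r.target_gene, r.reference_gene)],
        )
        for r in records
    ]


def fold_change(ddct, efficiency_base: float = 2.0):
    """Relative expression base^(−ΔΔCt); scalar in, scalar out (arrays OK)."""
    if not efficiency_base > 1.0:
        raise ConfigError(f"efficiency_base must be > 1, got {efficiency_base}")
    result = np.power(float(efficiency_base), -np.asarray(ddct, dtype=float))
    return float(result) if np.isscalar(ddct) or np.ndim(ddct) == 0 else result


def fold_profile(
    ddct_records: Iterable[DeltaDeltaCtRecord], efficiency_base: float = 2.0
) -> pd.Series:
    """Per-replicate folds as a Series indexed by (treatment, replicate, target)."""
    records = list(ddct_records)
    index = pd.MultiIndex.from_tuples(
        [(r.treatment, r.replicate, r.target_gene) for r in records],
        names=("treatment", "replicate", "target"),
    )
    return pd.Series(
        [fold_change(r.ddct, efficiency_base) for r in records], index=index, name="fold"
    )


def combine_reference_profiles(
    per_reference: Mapping[str, pd.Series],
) -> tuple[pd.Series, pd.DataFrame]:
    """Average per-replicate folds across reference genes.

    All profiles must be aligned on (treatment, replicate, target).  Returns
    the combined profile and a tidy report of the Pearson correlation
    between each pair of references' treatment-mean profiles — the
    stability check used to justify averaging (empty for one reference).
    """
    if not per_reference:
        raise ConfigError("at least one reference profile is required")
    names = list(per_reference)
    base_index = per_reference[names[0]].index
    for name in names[1:]:
        other = per_reference[name].index
        if len(other) != len(base_index) or set(other) != set(base_index):
            offending = sorted(
                set(map(tuple, other)).symmetric_difference(set(map(tuple, base_index)))
            )
            raise AlignmentError(
                f"reference profiles misaligned; offending keys: {offending[:10]}"
            )
    aligned = pd.concat(
        {name: per_reference[name].reindex(base_index) for name in names}, axis=1
    )
    combined = aligned.mean(axis=1).rename("fold")

    rows = []
    means = {
        name: aligned[name].groupby(level=["treatment", "target"]).mean()
        for name in names
    }
    for a, b in itertools.combinations(names, 2):
        x, y = means[a].to_numpy(), means[b].reindex(means[a].index).to_numpy()
        rows.append({"reference_a": a, "reference_b": b, "pearson_r": _pearson(x, y)})
    report = pd.DataFrame(rows, columns=["reference_a", "reference_b", "pearson_r"])
    return combined, report


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x**2).sum() * (y**2).sum())
    return float(np.nan) if denom == 0 else float((x * y).sum() / denom)


def summarize_expression(
    folds: pd.Series,
    design: DesignSpec,
    *,
    pin_control: bool = True,
    scale: str = "fold",
    per_reference: Mapping[str, pd.Series] | None = None,
) -> list[ExpressionEstimate]:
    """Per-(treatment, gene) mean ± SE of replicate folds.

    ``scale="fold"`` averages on the fold scale (arithmetic mean, SE =
    sd/√n).  ``scale="log2"`` averages log2 folds, giving symmetric
    intervals on the log scale.  With ``pin_control`` the control treatment
    is reported as exactly 1 ± 0 (0 ± 0 on the log2 scale), matching the
    convention that control expression is 1 by construction; the raw
    control scatter is available with ``pin_control=False``.  Groups with a
    single replicate get SE = NaN and a warning, never a silent 0.
    """
    if scale not in ("fold", "log2"):
        raise ConfigError(f"scale must be 'fold' or 'log2', got {scale!r}")
    control = tuple(design.control_treatment)
    values = np.log2(folds) if scale == "log2" else folds
    estimates: list[ExpressionEstimate] = []
    for (treatment, target), group in values.groupby(level=["treatment", "target"], sort=False):
        arr = group.to_numpy(dtype=float)
        n = arr.size
        if n == 0:
            raise DesignError(f"empty replicate group for {(treatment, target)}")
        mean = float(arr.mean())
        if n == 1:
            warnings.warn(
                f"single replicate for {(treatment, target)}: SE is undefined",
                stacklevel=2,
            )
            se = float("nan")
        else:
            se = float(arr.std(ddof=1) / np.sqrt(n))
        if pin_control and tuple(treatment) == control:
            mean, se = (1.0, 0.0) if scale == "fold" else (0.0, 0.0)
        per_ref = None
        if per_reference is not None:
            per_ref = {}
            for name, profile in per_reference.items():
                vals = np.log2(profile) if scale == "log2" else profile
                sub = vals.xs((treatment, target), level=["treatment", "target"]).to_numpy()
                per_ref[name] = (
                    float(sub.mean()),
                    float(sub.std(ddof=1) / np.sqrt(sub.size)) if sub.size > 1 else float("nan"),
                )
        estimates.append(
            ExpressionEstimate(
                treatment=tuple(treatment),
                target_gene=target,
                fold_mean=mean,
                fold_se=se,
                n=n,
                scale=scale,
                per_reference=per_ref,
            )
        )
    return estimates


def se_vs_control(estimate: ExpressionEstimate, control: ExpressionEstimate) -> float:
    """Standard error of a fold estimate *relative to the control mean*.

    The ΔΔCt normalization subtracts the control group's mean ΔCt, whose
    sampling error is shared by every replicate of a treatment and hence
    invisible to the within-treatment SE.  For inference about the fold
    difference from control, combine both scatters:
    √(SE_treatment² + SE_control²).  Use with unpinned, log2-scale
    summaries, where the control row's SE is its mean-ΔCt uncertainty.
    """
    return float(np.hypot(estimate.fold_se, control.fold_se))


def relative_expression(
    wells: Iterable[CtWell],
    design: DesignSpec,
    *,
    combine_mode: str = "mean-fold",
    pin_control: bool = True,
    scale: str = "fold",
) -> tuple[list[ExpressionEstimate], pd.DataFrame]:
    """Full pipeline: ΔCt → ΔΔCt → fold per reference → combine → summarize.

    ``combine_mode="mean-fold"`` averages the per-reference fold profiles
    (the default); ``"mean-ct"`` averages the reference Cts within each
    sample first and runs a single ΔΔCt pass against that pooled reference,
    which is what much instrument software does.  Returns the estimates and
    the cross-reference correlation report (empty for one reference or
    ``mean-ct`` mode).
    """
    wells = list(wells)
    refs = sorted(design.reference_genes)
    if combine_mode not in ("mean-fold", "mean-ct"):
        raise ConfigError(f"unknown combine_mode {combine_mode!r}")
    if combine_mode == "mean-ct" and len(refs) > 1:
        wells = _pool_reference_cts(wells, refs)
        refs = ["__pooled_reference__"]

    per_reference: dict[str, pd.Series] = {}
    for ref in refs:
        records, _ = delta_ct(wells, ref)
        ddct = delta_delta_ct(records, design.control_treatment)
        per_reference[ref] = fold_profile(ddct, design.efficiency_base)
    combined, report = combine_reference_profiles(per_reference)
    estimates = summarize_expression(
        combined,
        design,
        pin_control=pin_control,
        scale=scale,
        per_reference=per_reference if len(per_reference) > 1 else None,
    )
    return estimates, report


def _pool_reference_cts(wells: list[CtWell], refs: Sequence[str]) -> list[CtWell]:
    """Replace each sample's reference wells by their mean-Ct pooled well."""
    by_sample: dict[str, list[CtWell]] = {}
    out: list[CtWell] = []
    for w in wells:
        if w.gene_id in refs:
            by_sample.setdefault(w.sample_id, []).append(w)
        else:
            out.append(w)
    for sample, group in by_sample.items():
        cts = [w.ct for w in group]
        pooled = None if any(c is None for c in cts) else float(np.mean(cts))
        proto = group[0]
        out.append(
            CtWell(
                sample_id=sample,
                treatment=proto.treatment,
                replicate=proto.replicate,
                gene_id="__pooled_reference__",
                role=ROLE_REFERENCE,
                ct=pooled,
            )
        )
    return out


def estimates_to_frame(estimates: Iterable[ExpressionEstimate]) -> pd.DataFrame:
    """Flatten estimates into a tidy frame (factor levels, gene, mean, se, n)."""
    estimates = list(estimates)
    n_factors = len(estimates[0].treatment) if estimates else 0
    rows = []
    for e in estimates:
        row = {f"factor{i+1}": level for i, level in enumerate(e.treatment)}
        row.update(
            gene=e.target_gene, fold_mean=e.fold_mean, fold_se=e.fold_se, n=e.n
        )
        rows.append(row)
    cols = [f"factor{i+1}" for i in range(n_factors)] + [
        "gene",
        "fold_mean",
        "fold_se",
        "n",
    ]
    return pd.DataFrame(rows, columns=cols)


def _group_by(items, key):
    groups: dict = {}
    for item in items:
        groups.setdefault(key(item), []).append(item)
    return groups.items()
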