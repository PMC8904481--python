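"""Synthetic qPCR experiments with known ground truth.

The generator emulates a two-factor completely randomized design (by
default 3 × 5 treatment combinations, three biological replicates, two
internal-control genes) under the generative model the 2^−ΔΔCt estimator
assumes:

* every sample carries a shared random offset (RNA quantity / loading),
  cancelled exactly by ΔCt;
* reference Ct = reference baseline + sample offset + N(0, stability sd);
* target Ct = target baseline + sample offset − log2(true fold)
  + N(0, well noise sd), with the control treatment's true fold equal to 1.

Because every noise term is Gaussian on the cycle scale and the folds enter
through −log2(fold), the estimator's log2 output is unbiased for the true
log2 fold — which is exactly what the parameter-recovery tests check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ctio import ROLE_REFERENCE, ROLE_TARGET, CtWell, DesignSpec
from .errors import ConfigError


@dataclass(frozen=True)
class SynthSpec:
    """Ground truth and noise model for a simulated Ct experiment.

    ``true_folds`` maps target gene → {treatment tuple → fold change};
    treatments missing from a gene's map default to fold 1, and the control
    treatment must be 1 wherever stated.  ``reference_genes`` maps
    reference gene → (baseline Ct, stability sd).  ``sample_effect_sd`` is
    the spread of the shared per-sample offset (cycles) that ΔCt removes.
    ``dropout_rate`` turns wells into missing-Ct sentinels at random to
    exercise missing-data paths.
    """

    factor_levels: tuple[tuple[str, ...], ...] = (("0", "10", "20"), ("0", "5", "10", "15", "20"))
    factor_names: tuple[str, ...] = ("peg", "proline")
    control: tuple[str, ...] = ("0", "0")
    true_folds: Mapping[str, Mapping[tuple[str, ...], float]] = field(
        default_factory=lambda: {"geneA": {}}
    )
    reference_genes: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"actin": (18.0, 0.15), "ef1": (20.0, 0.15)}
    )
    target_baseline_ct: float = 25.0
    n_replicates: int = 3
    well_noise_sd: float = 0.2
    sample_effect_sd: float = 0.5
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        for sd_name, sd in (
            ("well_noise_sd", self.well_noise_sd),
            ("sample_effect_sd", self.sample_effect_sd),
        ):
            if sd < 0:
                raise ConfigError(f"{sd_name} must be >= 0, got {sd}")
        for ref, (_, sd) in self.reference_genes.items():
            if sd < 0:
                raise ConfigError(f"stability sd of {ref!r} must be >= 0")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must be in [0, 1)")
        if not self.reference_genes:
            raise ConfigError("at least one reference gene is required")
        control = tuple(self.control)
        if control not in self.treatments():
            raise ConfigError(f"control {control} is not a factor-level combination")
        for gene, fold_map in self.true_folds.items():
            for treatment, fold in fold_map.items():
                if not fold > 0:
                    raise ConfigError(f"fold for {gene!r} at {treatment} must be > 0")
            if fold_map.get(control, 1.0) != 1.0:
                raise ConfigError(f"control fold of {gene!r} must be 1")

    def treatments(self) -> list[tuple[str, ...]]:
        grids = np.meshgrid(*[np.arange(len(lv)) for lv in self.factor_levels], indexing="ij")
        combos = np.stack([g.ravel() for g in grids], axis=1)
        return [
            tuple(self.factor_levels[f][i] for f, i in enumerate(row)) for row in combos
        ]

    def true_fold(self, gene: str, treatment: tuple[str, ...]) -> float:
        return float(self.true_folds.get(gene, {}).get(tuple(treatment), 1.0))

    def design(self, alpha: float = 0.05) -> DesignSpec:
        """The matching DesignSpec for running the estimation pipeline."""
        return DesignSpec(
            factor_names=self.factor_names,
            control_treatment=self.control,
            reference_genes=frozenset(self.reference_genes),
            alpha=alpha,
        )


def simulate_ct_experiment(
    spec: SynthSpec, seed: int | None = None
) -> tuple[list[CtWell], pd.DataFrame]:
    """Draw one experiment: Ct wells plus the ground-truth fold table.

    Reproducible: the same spec and seed give byte-identical output.
    ``seed=None`` uses ``spec.seed``.  The truth frame has one row per
    (treatment, target gene) with the generating fold and its log2.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    wells: list[CtWell] = []
    truth_rows = []
    targets = sorted(spec.true_folds)
    refs = sorted(spec.reference_genes)
    for treatment in spec.treatments():
        for gene in targets:
            truth_rows.append(
                {
                    **{name: lvl for name, lvl in zip(spec.factor_names, treatment)},
                    "gene": gene,
                    "true_fold": spec.true_fold(gene, treatment),
                    "true_log2_fold": float(np.log2(spec.true_fold(gene, treatment))),
                }
            )
        for rep in range(1, spec.n_replicates + 1):
            sample_id = "s_" + "_".join(treatment) + f"_r{rep}"
            offset = rng.normal(0.0, spec.sample_effect_sd)
            for ref in refs:
                baseline, stability_sd = spec.reference_genes[ref]
                ct = baseline + offset + rng.normal(0.0, stability_sd)
                wells.append(
                    _well(spec, rng, sample_id, treatment, rep, ref, ROLE_REFERENCE, ct)
                )
            for gene in targets:
                ct = (
                    spec.target_baseline_ct
                    + offset
                    - np.log2(spec.true_fold(gene, treatment))
                    + rng.normal(0.0, spec.well_noise_sd)
                )
                wells.append(
                    _well(spec, rng, sample_id, treatment, rep, gene, ROLE_TARGET, ct)
                )
    truth = pd.DataFrame(truth_rows)
    return wells, truth


def _well(spec, rng, sample_id, treatment, rep, gene, role, ct) -> CtWell:
    if spec.dropout_rate > 0 and rng.random() < spec.dropout_rate:
        ct = None
    return CtWell(
        sample_id=sample_id,
        treatment=tuple(treatment),
        replicate=rep,
        gene_id=gene,
        role=role,
        ct=None if ct is None else float(ct),
    )


def fold_grid(
    treatments: Sequence[tuple[str, ...]],
    control: tuple[str, ...],
    folds: Sequence[float],
    seed: int = 0,
) -> dict[tuple[str, ...], float]:
    """Assign folds from a candidate set across non-control treatments.

    Cycles deterministically through ``folds`` after a seeded shuffle, so a
    simulated experiment exercises every effect size; the control stays 1.
    """
    rng = np.random.default_rng(seed)
    pool = list(folds)
    rng.shuffle(pool)
    mapping: dict[tuple[str, ...], float] = {tuple(control): 1.0}
    i = 0
    for t in treatments:
        t = tuple(t)
        if t == tuple(control):
            continue
        mapping[t] = float(pool[i % len(pool)])
        i += 1
    return mapping
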