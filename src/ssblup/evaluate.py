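"""Study orchestration and validation statistics.

Ties the modules together for one simulated replicate: build kinship and
genomic matrices, assemble the single-step MME in the requested
formulation, solve by PCG, and score GEBV of the validation animals
against their true breeding values with the regression coefficient
b = cov(TBV, GEBV)/var(GEBV) and the Pearson correlation r.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic import RegularizationSpec, base_allele_frequencies, center_and_scale
from .markercov import TraitWeights, average_weight_columns, build_vg_blocks, standardize_and_floor
from .mme import ModelSpec, assemble_dataset, split_solution, SingleStepOperator
from .pcg import build_block_preconditioner, pcg_solve
from .pedigree import inbreeding_and_a_inverse, validate_and_sort
from .simulate import SimulatedStudy
from .weights import (
    BayesAConfig, animal_model_ebv_and_reliability, bayesa_gibbs,
    bayesa_prior_scale, deregress, weights_from_variances,
)

MODELS = ("noweights", "common:P", "common:A", "common:AP", "trait_specific")

__all__ = [
    "MODELS",
    "ValidationResult",
    "SolveResult",
    "validation_stats",
    "replicate_summary_and_weight_sd",
    "prepare_study",
    "estimate_marker_weights",
    "solve_study_model",
]


@dataclass
class ValidationResult:
    trait: str
    b: float
    r: float
    group: str
    n_animals: int


def validation_stats(tbv: np.ndarray, gebv: np.ndarray, trait_names: list[str],
                     group: str = "validation") -> list[ValidationResult]:
    """Per-trait regression of TBV on GEBV and their correlation."""
    tbv = np.atleast_2d(np.asarray(tbv, dtype=float))
    gebv = np.atleast_2d(np.asarray(gebv, dtype=float))
    if tbv.shape != gebv.shape or tbv.shape[0] == 0:
        raise ValueError("TBV and GEBV must be non-empty and paired")
    out = []
    for t, name in enumerate(trait_names):
        var = gebv[:, t].var(ddof=0)
        if var == 0:
            raise ValueError(f"zero-variance GEBV for trait {name}")
        cov = np.cov(tbv[:, t], gebv[:, t], ddof=0)[0, 1]
        r = float(np.corrcoef(tbv[:, t], gebv[:, t])[0, 1])
        out.append(ValidationResult(name, float(cov / var), r, group, tbv.shape[0]))
    return out


def replicate_summary_and_weight_sd(
    results: list[list[ValidationResult]],
    weights: list[np.ndarray] | None = None,
) -> pd.DataFrame:
    """Means and standard errors over replicates, plus mean weight SD.

    ``results`` holds one list of per-trait validation results per
    replicate; ``weights`` optionally one marker-weight vector per
    replicate, whose per-replicate standard deviations are averaged.
    """
    rows = []
    traits = [v.trait for v in results[0]]
    for t, name in enumerate(traits):
        bs = np.array([rep[t].b for rep in results])
        rs = np.array([rep[t].r for rep in results])
        nrep = len(results)
        se = (lambda x: float(x.std(ddof=1) / np.sqrt(nrep)) if nrep > 1 else np.nan)
        rows.append({
            "trait": name,
            "b": float(bs.mean()), "b_se": se(bs),
            "r": float(rs.mean()), "r_se": se(rs),
        })
    df = pd.DataFrame(rows)
    if weights is not None:
        df["weight_sd"] = float(np.mean([np.std(w, ddof=0) for w in weights]))
    return df


# ------------------------------------------------------------ pipeline

@dataclass
class PreparedStudy:
    """Kinship, centered genotypes and assembled dataset for one panel."""

    study: SimulatedStudy
    panel: str
    spec: ModelSpec
    kin: object
    z_c: np.ndarray
    s: float
    dataset: object
    validation_slice: np.ndarray  # pedigree positions


def prepare_study(study: SimulatedStudy, panel: str = "qtl0",
                  cspec: RegularizationSpec | None = None,
                  freq_method: str = "known") -> PreparedStudy:
    cfg = study.config
    cspec = cspec or RegularizationSpec("Cw", w=0.05)
    spec = ModelSpec(g0=cfg.g0_true(), r0=cfg.r0_true(), cspec=cspec,
                     trait_names=study.trait_names)
    ped = validate_and_sort(study.ped)
    kin = inbreeding_and_a_inverse(ped)
    geno = study.genotypes[panel]
    geno.p = base_allele_frequencies(
        geno.counts, method=freq_method,
        known_p=study.base_freq[panel] if freq_method == "known" else None,
    )
    z_c, s = center_and_scale(geno)
    # align genotype rows with the pedigree's genotyped block
    gen_labels = ped.labels[ped.genotyped_index]
    lut = {lab: i for i, lab in enumerate(geno.ids.tolist())}
    z_c = z_c[[lut[lab] for lab in gen_labels.tolist()]]
    dataset = assemble_dataset(ped, study.phenotypes, spec)
    validation = ped.position_of(study.ped.labels[study.validation])
    return PreparedStudy(study=study, panel=panel, spec=spec, kin=kin,
                         z_c=z_c, s=s, dataset=dataset, validation_slice=validation)


def estimate_marker_weights(
    prep: PreparedStudy,
    config: BayesAConfig | None = None,
    use_numba: bool = True,
) -> tuple[TraitWeights, dict[str, np.ndarray]]:
    """Two-step weight estimation on one prepared panel.

    Pedigree-BLUP EBV and reliabilities → deregressed proofs for
    genotyped animals with own or progeny phenotypes → one single-trait
    weighted BayesA per trait → posterior mean marker variances scaled
    to mean 1.
    """
    config = config or BayesAConfig()
    study, spec, ped = prep.study, prep.spec, prep.dataset.ped
    ebv, rel = animal_model_ebv_and_reliability(ped, study.phenotypes, prep.kin, spec)
    recs = deregress(ebv, rel, ped, study.phenotypes, spec)
    drp = pd.DataFrame([r.__dict__ for r in recs])
    gen_labels = ped.labels[ped.genotyped_index]
    row_of = {lab: i for i, lab in enumerate(gen_labels.tolist())}

    cols = {}
    for t, trait in enumerate(spec.trait_names):
        sub = drp[(drp["trait"] == trait) & drp["animal"].isin(row_of)]
        if len(sub) == 0:
            raise ValueError(f"no genotyped animals with deregressed proofs for {trait}")
        rows = [row_of[a] for a in sub["animal"]]
        cfg_t = BayesAConfig(
            nu=config.nu,
            scale=bayesa_prior_scale(spec.g0[t, t], prep.s, config.nu),
            chain=config.chain, burn_in=config.burn_in, seed=config.seed + t,
        )
        sig2, _ = bayesa_gibbs(
            sub["drp"].to_numpy(), sub["weight"].to_numpy(), prep.z_c[rows],
            cfg_t, use_numba=use_numba,
        )
        cols[trait] = weights_from_variances(sig2)
    d = np.column_stack([standardize_and_floor(cols[t]) for t in spec.trait_names])
    return TraitWeights(d), cols


@dataclass
class SolveResult:
    model: str
    panel: str
    solution: dict[str, np.ndarray] = field(repr=False)
    gebv_validation: np.ndarray = field(repr=False)
    tbv_validation: np.ndarray = field(repr=False)
    iterations: int = 0
    final_cr: float = np.nan
    stats: list[ValidationResult] = field(default_factory=list)


def solve_study_model(
    prep: PreparedStudy,
    model: str = "noweights",
    weights: TraitWeights | None = None,
    tol: float = 1e-7,
    maxiter: int = 50_000,
) -> SolveResult:
    """Solve one single-step model configuration by preconditioned CG.

    ``model``: "noweights" (equal weights), "common:P"/"common:A"
    (one trait's weights for both traits), "common:AP" (their average),
    or "trait_specific" (each trait its own column of ``weights``).
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    spec = prep.spec
    m = prep.z_c.shape[1]
    scale = spec.cspec.marker_scale(prep.s)

    if model == "noweights":
        op = SingleStepOperator(prep.dataset, prep.kin, prep.z_c, "common",
                                b_diag=np.full(m, scale))
        used_weights = np.ones(m)
    elif model.startswith("common:"):
        if weights is None:
            raise ValueError("common-weight models need estimated weights")
        which = model.split(":")[1]
        if which == "P":
            wcol = weights.d[:, 0]
        elif which == "A":
            wcol = weights.d[:, 1]
        else:
            wcol = average_weight_columns(weights.d[:, 0], weights.d[:, 1])
        op = SingleStepOperator(prep.dataset, prep.kin, prep.z_c, "common",
                                b_diag=wcol * scale)
        used_weights = wcol
    else:
        if weights is None:
            raise ValueError("trait-specific model needs estimated weights")
        vg = build_vg_blocks(spec.g0, weights, prep.s, spec.cspec)
        op = SingleStepOperator(prep.dataset, prep.kin, prep.z_c, "trait_specific", vg=vg)
        used_weights = weights.d

    pre = build_block_preconditioner(op)
    trace = pcg_solve(op, op.rhs, pre, tol=tol, maxiter=maxiter)
    sol = split_solution(trace.solution, prep.dataset, m)

    val = prep.validation_slice
    gebv = sol["u"][val]
    ped = prep.dataset.ped
    tbv = prep.study.tbv[prep.study.ped.position_of(ped.labels[val])]
    stats = validation_stats(tbv, gebv, spec.trait_names)
    res = SolveResult(model=model, panel=prep.panel, solution=sol,
                      gebv_validation=gebv, tbv_validation=tbv,
                      iterations=trace.iterations, final_cr=float(trace.cr_history[-1]),
                      stats=stats)
    res.used_weights = used_weights
    return res
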