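"""Shared fixtures: random pedigrees and small assembled single-step systems."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from ssblup.genomic import GenotypeMatrix, RegularizationSpec, base_allele_frequencies, center_and_scale
from ssblup.markercov import MarkerCovarianceBlocks, TraitWeights, build_vg_blocks, standardize_and_floor
from ssblup.mme import Dataset, ModelSpec, assemble_dataset
from ssblup.pedigree import UNKNOWN, KinshipComponents, Pedigree, inbreeding_and_a_inverse, validate_and_sort

G0_2TRAIT = np.array([[0.3, -0.05196], [-0.05196, 0.1]])
R0_2TRAIT = np.diag([0.7, 0.9])


def make_random_pedigree(n=30, n_founders=8, geno_frac=0.4, seed=0) -> Pedigree:
    """Random multi-generation pedigree with a genotyped subset."""
    r = np.random.default_rng(seed)
    sire = np.full(n, UNKNOWN, dtype=np.int64)
    dam = np.full(n, UNKNOWN, dtype=np.int64)
    sex = np.array(["M", "F"] * (n // 2 + 1), dtype=object)[:n]
    for i in range(n_founders, n):
        males = [j for j in range(i) if sex[j] == "M"]
        females = [j for j in range(i) if sex[j] == "F"]
        sire[i] = r.choice(males)
        dam[i] = r.choice(females)
    gen = np.zeros(n, dtype=np.int64)
    for i in range(n):
        if sire[i] != UNKNOWN:
            gen[i] = max(gen[sire[i]], gen[dam[i]]) + 1
    genotyped = r.random(n) < geno_frac
    genotyped[-3:] = True
    return Pedigree(
        labels=np.arange(1, n + 1), sire=sire, dam=dam, sex=sex,
        generation=gen, genotyped=genotyped, phenotyped=np.ones(n, dtype=bool),
    )


@dataclass
class SmallSystem:
    """A complete desk-scale two-trait single-step problem."""

    ped: Pedigree
    kin: KinshipComponents
    spec: ModelSpec
    dataset: Dataset
    z_c: np.ndarray
    s: float
    b_equal: np.ndarray          # equal-weight B diagonal
    weights: TraitWeights        # random trait-specific weights
    vg: MarkerCovarianceBlocks
    vg_unit: MarkerCovarianceBlocks


def make_small_system(n=30, n_founders=8, m=20, seed=0, kind="Cw",
                      missing_frac=0.3) -> SmallSystem:
    rng = np.random.default_rng(seed + 1000)
    ped = validate_and_sort(make_random_pedigree(n, n_founders, 0.4, seed))
    kin = inbreeding_and_a_inverse(ped)
    ng = ped.genotyped_index.size
    counts = rng.integers(0, 3, size=(ng, m))
    geno = GenotypeMatrix(ids=np.arange(ng), counts=counts)
    geno.p = base_allele_frequencies(counts, "observed_mean")
    z_c, s = center_and_scale(geno)
    cspec = RegularizationSpec(kind)
    spec = ModelSpec(G0_2TRAIT, R0_2TRAIT, cspec)
    phen = pd.DataFrame({
        "animal": ped.labels,
        "trait1": rng.standard_normal(n),
        "trait2": rng.standard_normal(n),
    })
    phen.loc[rng.random(n) < missing_frac, "trait2"] = np.nan
    dataset = assemble_dataset(ped, phen, spec)
    raw = rng.gamma(1.0, 1.0, size=(m, 2))
    weights = TraitWeights(np.column_stack([
        standardize_and_floor(raw[:, 0]), standardize_and_floor(raw[:, 1])
    ]))
    vg = build_vg_blocks(spec.g0, weights, s, cspec)
    vg_unit = build_vg_blocks(spec.g0, TraitWeights.ones(m, 2), s, cspec)
    b_equal = np.full(m, cspec.marker_scale(s))
    return SmallSystem(ped=ped, kin=kin, spec=spec, dataset=dataset, z_c=z_c, s=s,
                       b_equal=b_equal, weights=weights, vg=vg, vg_unit=vg_unit)


@pytest.fixture
def small_system() -> SmallSystem:
    return make_small_system()
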