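"""Round-trip of a simulated study through the standard text files.

A study directory holds: pedigree.tsv, phenotypes.tsv, tbv.tsv, and per
marker panel genotypes_<panel>.raw (PLINK .raw dialect) plus
freq_<panel>.tsv with the true base allele frequencies.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genomic import read_genotypes, write_plink_raw, write_frequencies_tsv, read_frequencies_tsv
from .pedigree import read_pedigree_tsv, write_pedigree_tsv
from .simulate import SimConfig, SimulatedStudy

__all__ = ["write_study", "read_study"]

_TRAITS = ["production", "adaptation"]


def write_study(study: SimulatedStudy, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_pedigree_tsv(study.ped, path / "pedigree.tsv")
    study.phenotypes.to_csv(path / "phenotypes.tsv", sep="\t", index=False)
    tbv = pd.DataFrame({"animal": study.ped.labels})
    for t, name in enumerate(_TRAITS):
        tbv[name] = study.tbv[:, t]
    tbv.to_csv(path / "tbv.tsv", sep="\t", index=False)
    for panel, geno in study.genotypes.items():
        write_plink_raw(geno, path / f"genotypes_{panel}.raw")
        write_frequencies_tsv(study.base_freq[panel], path / f"freq_{panel}.tsv")


def read_study(path, config: SimConfig) -> SimulatedStudy:
    """Rebuild a study from its directory (validation = genotyped, last generation)."""
    path = Path(path)
    ped = read_pedigree_tsv(path / "pedigree.tsv")
    phen = pd.read_csv(path / "phenotypes.tsv", sep="\t", dtype={"animal": str})
    tbv_df = pd.read_csv(path / "tbv.tsv", sep="\t", dtype={"animal": str})
    order = ped.position_of(tbv_df["animal"].to_numpy())
    tbv = np.zeros((ped.n, len(_TRAITS)))
    tbv[order] = tbv_df[_TRAITS].to_numpy()
    genotypes, base_freq, panels = {}, {}, {}
    for f in sorted(path.glob("genotypes_*.raw")):
        panel = f.stem.replace("genotypes_", "")
        geno = read_genotypes(f)
        geno.ids = geno.ids.astype(str)
        genotypes[panel] = geno
        base_freq[panel] = read_frequencies_tsv(path / f"freq_{panel}.tsv")["p"].to_numpy()
        panels[panel] = np.arange(geno.m)
    validation = np.flatnonzero(ped.genotyped & (ped.generation == ped.generation.max()))
    return SimulatedStudy(
        ped=ped, genotypes=genotypes, base_freq=base_freq, panel_loci=panels,
        phenotypes=phen, tbv=tbv, qtl_effects=np.zeros((0, len(_TRAITS))),
        validation=validation, config=config,
    )
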