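"""Plain-text and binary-container I/O for maps, genotypes and configs."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

from .breeding import ScenarioConfig
from .genome import GenomeMap

__all__ = [
    "save_config",
    "load_config",
    "export_map_tsv",
    "export_genotypes_text",
    "save_founders_npz",
    "load_founders_npz",
]


def save_config(config: ScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


def load_config(path) -> ScenarioConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(ScenarioConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("eval_years", "gain_early_years", "gain_late_years"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    cfg = ScenarioConfig(**raw)
    cfg.validate()
    return cfg


def export_map_tsv(gmap: GenomeMap, path) -> None:
    """Tab-separated (chromosome, locus id, position cM)."""
    gmap.to_dataframe().to_csv(path, sep="\t", index=False)


def export_genotypes_text(haplotypes: np.ndarray, ids: np.ndarray, path) -> None:
    """PLINK-style transposed text: one locus per row, alleles 0/1 per haplotype.

    Columns: locus index followed by the two haplotype alleles of every
    individual in ``ids`` order.
    """
    n, _, L = haplotypes.shape
    with open(path, "w") as fh:
        fh.write("locus\t" + "\t".join(f"{i}_m\t{i}_p" for i in ids) + "\n")
        flat = haplotypes.transpose(2, 0, 1).reshape(L, 2 * n)
        for locus in range(L):
            fh.write(f"{locus}\t" + "\t".join(map(str, flat[locus])) + "\n")


def save_founders_npz(path, haplotypes: np.ndarray, gmap: GenomeMap) -> None:
    """Binary container with one haplotype dataset per chromosome."""
    arrays = {
        "chrom_length_cM": gmap.chrom_length_cM,
        "chrom": gmap.chrom,
        "pos_cM": gmap.pos_cM,
    }
    for c, sl in enumerate(gmap.chromosome_slices()):
        arrays[f"haplotypes_chr{c}"] = haplotypes[:, :, sl]
    np.savez_compressed(path, **arrays)


def load_founders_npz(path) -> tuple[np.ndarray, GenomeMap]:
    with np.load(path) as data:
        gmap = GenomeMap(
            chrom=data["chrom"], pos_cM=data["pos_cM"], chrom_length_cM=data["chrom_length_cM"]
        )
        parts = [data[f"haplotypes_chr{c}"] for c in range(gmap.n_chromosomes)]
    return np.concatenate(parts, axis=2), gmap


def export_records_tsv(data, path) -> None:
    """Phenotypic record table: animal, environment, year, value."""
    import pandas as pd

    pd.DataFrame(
        {
            "animal": data.animal,
            "environment": np.where(data.env == 0, "B", "C"),
            "year": data.year,
            "value": data.y,
        }
    ).to_csv(path, sep="\t", index=False)


def export_gebv_tsv(ids: np.ndarray, gebv: np.ndarray, path) -> None:
    """GEBV table: animal, gebv_B, gebv_C."""
    import pandas as pd

    pd.DataFrame({"animal": ids, "gebv_B": gebv[:, 0], "gebv_C": gebv[:, 1]}).to_csv(
        path, sep="\t", index=False
    )


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
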