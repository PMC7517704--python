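"""Individuals, cohorts and pedigree bookkeeping.

The breeding loop works on columnar cohort arrays for speed; ``Individual``
is the record-level view used by the small-scale API (``make_offspring``)
and by tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeMap, TraitArchitecture, sample_gametes, true_breeding_values

__all__ = ["Individual", "make_offspring", "Pedigree"]

ENV_UNPLACED, ENV_B, ENV_C = -1, 0, 1


@dataclass
class Individual:
    """One fish: haplotypes, pedigree links and trait values.

    ``environment`` is -1 while unplaced, 0 for the breeding environment B
    and 1 for the commercial environment C.  A phenotype exists only for the
    environment the fish was placed in, and GEBV only once genotyped.
    """

    id: int
    sire_id: int
    dam_id: int
    sex: str  # "M" or "F"
    birth_year: int
    haplotypes: np.ndarray  # (2, L) uint8
    tbv_B: float = np.nan
    tbv_C: float = np.nan
    environment: int = ENV_UNPLACED
    phenotype: float = np.nan
    genotyped: bool = False
    gebv_B: float = np.nan
    gebv_C: float = np.nan


def make_offspring(
    sire: Individual,
    dam: Individual,
    gmap: GenomeMap,
    sex: str,
    birth_year: int,
    rng: np.random.Generator,
    arch: TraitArchitecture | None = None,
    id: int = -1,
) -> Individual:
    """One meiosis from each parent; pedigree links and TBVs recorded."""
    if sire.id == dam.id:
        raise ValueError("selfing is not part of the design: sire and dam must differ")
    g_s = sample_gametes(sire.haplotypes, gmap, rng)
    g_d = sample_gametes(dam.haplotypes, gmap, rng)
    haplos = np.stack([g_s, g_d]).astype(np.uint8)
    child = Individual(
        id=id, sire_id=sire.id, dam_id=dam.id, sex=sex, birth_year=birth_year, haplotypes=haplos
    )
    if arch is not None:
        child.tbv_B, child.tbv_C = true_breeding_values(haplos, arch)
    return child


class Pedigree:
    """Append-only pedigree of all simulated fish.

    Founders carry parent id -1.  Rows are appended in birth order, so the
    pedigree is topologically sorted by construction.
    """

    def __init__(self) -> None:
        self._blocks: list[dict[str, np.ndarray]] = []

    def append(
        self,
        ids: np.ndarray,
        sire: np.ndarray,
        dam: np.ndarray,
        birth_year: int,
        sex_male: np.ndarray,
        env: np.ndarray,
        genotyped: np.ndarray | None = None,
    ) -> None:
        n = len(ids)
        self._blocks.append(
            {
                "id": np.asarray(ids, dtype=np.int64),
                "sire": np.asarray(sire, dtype=np.int64),
                "dam": np.asarray(dam, dtype=np.int64),
                "birth_year": np.full(n, birth_year, dtype=np.int64),
                "male": np.asarray(sex_male, dtype=bool),
                "env": np.asarray(env, dtype=np.int64),
                "genotyped": (
                    np.zeros(n, dtype=bool) if genotyped is None else np.asarray(genotyped, dtype=bool)
                ),
            }
        )

    def mark_genotyped(self, ids: np.ndarray) -> None:
        wanted = set(int(i) for i in ids)
        for blk in self._blocks:
            mask = np.fromiter((int(i) in wanted for i in blk["id"]), dtype=bool, count=len(blk["id"]))
            blk["genotyped"] |= mask

    def to_dataframe(self) -> pd.DataFrame:
        if not self._blocks:
            return pd.DataFrame(
                columns=["id", "sire", "dam", "birth_year", "male", "env", "genotyped"]
            )
        return pd.DataFrame(
            {k: np.concatenate([b[k] for b in self._blocks]) for k in self._blocks[0]}
        )

    def to_tsv(self, path) -> None:
        df = self.to_dataframe()
        df["sex"] = np.where(df.pop("male"), "M", "F")
        df["environment"] = df.pop("env").map({ENV_UNPLACED: "-", ENV_B: "B", ENV_C: "C"})
        df.to_csv(path, sep="\t", index=False)


class KinshipTracker:
    """Exact pedigree kinship among the individuals that can become parents.

    Tracks the coancestry matrix over founders and every selected animal.
    The inbreeding coefficient of an offspring equals the kinship of its
    parents, so per-cohort mean inbreeding follows from the mating list
    without storing relationships for whole 20,000-fish cohorts.
    """

    def __init__(self, founder_ids: np.ndarray) -> None:
        n = len(founder_ids)
        self._index: dict[int, int] = {int(i): k for k, i in enumerate(founder_ids)}
        self._K = np.eye(n) * 0.5

    def __contains__(self, id_: int) -> bool:
        return int(id_) in self._index

    def kinship(self, id_a: int, id_b: int) -> float:
        return float(self._K[self._index[int(id_a)], self._index[int(id_b)]])

    def inbreeding_of_offspring(self, sire_ids: np.ndarray, dam_ids: np.ndarray) -> np.ndarray:
        si = np.array([self._index[int(i)] for i in sire_ids])
        di = np.array([self._index[int(i)] for i in dam_ids])
        return self._K[si, di]

    def add(self, ids: np.ndarray, sire_ids: np.ndarray, dam_ids: np.ndarray) -> None:
        """Register new individuals whose parents are already tracked."""
        K = self._K
        n_old = K.shape[0]
        m = len(ids)
        si = np.array([self._index[int(i)] for i in sire_ids], dtype=np.int64)
        di = np.array([self._index[int(i)] for i in dam_ids], dtype=np.int64)
        Knew = np.empty((n_old + m, n_old + m))
        Knew[:n_old, :n_old] = K
        cross = 0.5 * (K[si, :] + K[di, :])  # (m, n_old)
        Knew[n_old:, :n_old] = cross
        Knew[:n_old, n_old:] = cross.T
        # among the new individuals: quarter-sum of parental kinships
        block = 0.25 * (K[np.ix_(si, si)] + K[np.ix_(si, di)] + K[np.ix_(di, si)] + K[np.ix_(di, di)])
        self_k = 0.5 * (1.0 + K[si, di])
        block[np.arange(m), np.arange(m)] = self_k
        Knew[n_old:, n_old:] = block
        for k, i in enumerate(ids):
            self._index[int(i)] = n_old + k
        self._K = Knew
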