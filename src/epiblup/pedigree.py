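"""Pedigree container and stochastic pedigree simulation.

A pedigree is an ordered list of ``(animal, sire, dam)`` records with
unknown parents stored as ``None``. Records are topologically ordered:
every parent appears as an animal record before any of its offspring,
which also guarantees acyclicity. Founders have both parents unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN = None


@dataclass
class Pedigree:
    """Topologically ordered pedigree.

    Parameters
    ----------
    records : list of (animal_id, sire_id or None, dam_id or None)
    generation_of : dict mapping animal_id -> non-negative generation index
    """

    records: list[tuple[str, str | None, str | None]]
    generation_of: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for animal, sire, dam in self.records:
            if animal in seen:
                raise ValueError(f"duplicate animal id {animal!r}")
            for parent in (sire, dam):
                if parent is not None and parent not in seen:
                    raise ValueError(
                        f"parent {parent!r} of {animal!r} does not appear "
                        "earlier in the pedigree (cycle or missing record)"
                    )
            if animal in (sire, dam):
                raise ValueError(f"animal {animal!r} is its own parent")
            seen.add(animal)
        if not self.generation_of:
            self.generation_of = self._infer_generations()

    def _infer_generations(self) -> dict[str, int]:
        gen: dict[str, int] = {}
        for animal, sire, dam in self.records:
            parents = [p for p in (sire, dam) if p is not None]
            gen[animal] = 0 if not parents else 1 + max(gen[p] for p in parents)
        return gen

    @property
    def animal_ids(self) -> list[str]:
        return [rec[0] for rec in self.records]

    @property
    def n_animals(self) -> int:
        return len(self.records)

    def founders(self) -> list[str]:
        return [a for a, s, d in self.records if s is None and d is None]

    def parents_of(self, animal: str) -> tuple[str | None, str | None]:
        for a, s, d in self.records:
            if a == animal:
                return s, d
        raise KeyError(animal)

    # --- I/O -----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Three-column frame with 0 encoding an unknown parent."""
        return pd.DataFrame(
            [(a, s or "0", d or "0") for a, s, d in self.records],
            columns=["animal_id", "sire_id", "dam_id"],
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        recs = []
        for a, s, d in df.itertuples(index=False):
            sire = None if pd.isna(s) or str(s) in ("0", "") else str(s)
            dam = None if pd.isna(d) or str(d) in ("0", "") else str(d)
            recs.append((str(a), sire, dam))
        return cls(recs)

    @classmethod
    def read_csv(cls, path) -> "Pedigree":
        return cls.from_frame(pd.read_csv(path, dtype=str))


def simulate_pedigree(
    n_founders: int,
    n_generations: int,
    matings_per_generation: int,
    offspring_per_mating: int,
    full_sib_mating_fraction: float = 0.0,
    seed: int = 0,
) -> Pedigree:
    """Simulate a random-mating pedigree, optionally with full-sib matings.

    Each generation draws ``matings_per_generation`` pairs from the previous
    generation; a fraction of matings pairs two full sibs, which produces
    inbred offspring (F = 0.25 for the offspring of non-inbred full sibs).

    Parameters
    ----------
    n_founders : number of unrelated, non-inbred base animals (>= 2)
    n_generations : generations of offspring to append (0 = founders only)
    matings_per_generation : distinct matings drawn per generation
    offspring_per_mating : full sibs produced per mating
    full_sib_mating_fraction : proportion of matings between full sibs,
        where such pairs exist in the parental generation
    seed : RNG seed; same seed reproduces the pedigree exactly
    """
    if n_founders < 2:
        raise ValueError("n_founders must be >= 2")
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    if n_generations > 0 and matings_per_generation < 1:
        raise ValueError("matings_per_generation must be >= 1 when generations are simulated")
    if offspring_per_mating < 1:
        raise ValueError("offspring_per_mating must be >= 1")
    if not 0.0 <= full_sib_mating_fraction <= 1.0:
        raise ValueError("full_sib_mating_fraction must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    records: list[tuple[str, str | None, str | None]] = []
    generation: dict[str, int] = {}
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"I{counter:05d}"

    current = []
    # parents_of_current maps id -> (sire, dam) for full-sib detection
    parent_pair: dict[str, tuple[str, str] | None] = {}
    for _ in range(n_founders):
        a = new_id()
        records.append((a, None, None))
        generation[a] = 0
        parent_pair[a] = None
        current.append(a)

    for gen in range(1, n_generations + 1):
        # group previous generation into full-sib families of size >= 2
        families: dict[tuple[str, str], list[str]] = {}
        for a in current:
            pp = parent_pair[a]
            if pp is not None:
                families.setdefault(pp, []).append(a)
        sib_groups = [g for g in families.values() if len(g) >= 2]

        next_gen: list[str] = []
        for _ in range(matings_per_generation):
            use_sibs = sib_groups and rng.random() < full_sib_mating_fraction
            if use_sibs:
                group = sib_groups[rng.integers(len(sib_groups))]
                sire, dam = rng.choice(group, size=2, replace=False)
            else:
                sire, dam = rng.choice(current, size=2, replace=False)
            for _ in range(offspring_per_mating):
                child = new_id()
                records.append((child, str(sire), str(dam)))
                generation[child] = gen
                parent_pair[child] = (str(sire), str(dam))
                next_gen.append(child)
        current = next_gen

    return Pedigree(records, generation)
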