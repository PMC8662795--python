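"""Phylostratum ladders: ranked lineage strata used to date gene birth.

A phylostratigraphic ladder orders the clades on the path from the root of
the Tree of Life down to a focal species.  Rank 1 is the oldest stratum
(e.g. cellular organisms), the highest rank contains the focal species
alone.  Every subject genome used in the homology search belongs to exactly
one stratum; a gene is dated to the oldest stratum in which a homolog is
detectable.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = ["Stratum", "PhylostratumLadder"]


@dataclass(frozen=True)
class Stratum:
    """One rung of the ladder.

    Parameters
    ----------
    rank : int
        1-based position; rank 1 is the oldest clade.
    label : str
        Clade name, e.g. ``"Viridiplantae"``.
    genomes : frozenset of str
        Subject-genome identifiers whose earliest shared ancestor with the
        focal species is this stratum.
    duration_my : float, optional
        Length of the branch interval in million years (the ``T`` of the
        fixation rate ``r = N / T``).
    node_age_my : float, optional
        Age of the stratum's basal node in million years.
    """

    rank: int
    label: str
    genomes: frozenset = field(default_factory=frozenset)
    duration_my: float | None = None
    node_age_my: float | None = None


class PhylostratumLadder:
    """Ordered collection of strata with genome-to-rank resolution."""

    def __init__(self, strata: Sequence[Stratum]):
        strata = sorted(strata, key=lambda s: s.rank)
        if not strata:
            raise ValueError("ladder needs at least one stratum")
        ranks = [s.rank for s in strata]
        if ranks != list(range(1, len(strata) + 1)):
            raise ValueError(
                f"stratum ranks must be 1..K with no gaps, got {ranks}"
            )
        seen: dict[str, int] = {}
        for s in strata:
            for g in s.genomes:
                if g in seen:
                    raise ValueError(
                        f"genome {g!r} appears in strata {seen[g]} and {s.rank}"
                    )
                seen[g] = s.rank
            if s.duration_my is not None and s.duration_my <= 0:
                raise ValueError(
                    f"stratum {s.rank} has non-positive duration {s.duration_my}"
                )
        self.strata: tuple[Stratum, ...] = tuple(strata)
        self._genome_rank = seen

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.strata)

    def __iter__(self):
        return iter(self.strata)

    def __getitem__(self, rank: int) -> Stratum:
        if not 1 <= rank <= len(self.strata):
            raise KeyError(f"rank {rank} outside 1..{len(self.strata)}")
        return self.strata[rank - 1]

    @property
    def max_rank(self) -> int:
        """K, the youngest (focal-species) rank."""
        return len(self.strata)

    @property
    def focal_genomes(self) -> frozenset:
        """Genomes of the youngest stratum (the focal species itself)."""
        return self.strata[-1].genomes

    def rank_of(self, genome: str) -> int:
        """Resolve a subject genome to its stratum rank.

        Raises
        ------
        KeyError
            If the genome is not present in any stratum; the message names
            the offending genome.
        """
        try:
            return self._genome_rank[genome]
        except KeyError:
            raise KeyError(
                f"subject genome {genome!r} is not in the ladder"
            ) from None

    @property
    def genome_ranks(self) -> Mapping[str, int]:
        return dict(self._genome_rank)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "PhylostratumLadder":
        strata = [
            Stratum(
                rank=int(r["rank"]),
                label=str(r.get("label", f"PS{r['rank']}")),
                genomes=frozenset(r.get("genomes", ())),
                duration_my=r.get("duration_my"),
                node_age_my=r.get("node_age_my"),
            )
            for r in records
        ]
        return cls(strata)

    @classmethod
    def from_file(cls, path: str | Path) -> "PhylostratumLadder":
        """Read a YAML or JSON ladder config (list of stratum records)."""
        text = Path(path).read_text()
        data = (
            json.loads(text)
            if str(path).endswith(".json")
            else yaml.safe_load(text)
        )
        if isinstance(data, Mapping) and "strata" in data:
            data = data["strata"]
        return cls.from_records(data)

    def to_records(self) -> list[dict]:
        return [
            {
                "rank": s.rank,
                "label": s.label,
                "genomes": sorted(s.genomes),
                "duration_my": s.duration_my,
                "node_age_my": s.node_age_my,
            }
            for s in self.strata
        ]

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_records(), indent=1))
        else:
            path.write_text(yaml.safe_dump(self.to_records(), sort_keys=False))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"PhylostratumLadder(K={self.max_rank}, "
            f"genomes={len(self._genome_rank)})"
        )
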