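"""Synthetic inputs with recorded ground truth for every pipeline stage.

The generators emulate the evidence the real pipeline consumes — ranked
species ladders, homology-hit tables, cross-species orthologous regions
with planted ORF-disabling lesions, gene x sample FPKM matrices with
age-biased and tissue-specific expression, and CDS pairs evolved under a
planted Ka/Ks — without requiring any genome download.  Every generator
is a pure function of (parameters, seed): a global seed is expanded into
per-component streams through a fixed component counter, so outputs are
byte-identical across reruns and stable when unrelated parameters change.

What the generators do NOT emulate: genome structure (introns, repeats,
synteny), alignment-tool artefacts, read-level noise.  Recovery results on
these inputs therefore demonstrate correctness of the inference logic, not
robustness to real-data noise beyond the modelled miss/spurious rates.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .denovo import CodingGene, OriginationEvent, STOP_CODONS
from .kaks import _codon_sites  # standard NG86 site definition
from .ladder import PhylostratumLadder, Stratum

__all__ = [
    "SimulationTruth",
    "DenovoLocus",
    "simulate_ladder",
    "simulate_hit_tables",
    "simulate_denovo_loci",
    "simulate_expression",
    "simulate_divergence",
]

# fixed per-component stream ids for the counter-based seed expansion
_STREAMS = {
    "ladder": 11,
    "hits": 12,
    "denovo": 13,
    "expression": 14,
    "divergence": 15,
}

_BASES = "ACGT"
_SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in STOP_CODONS
)


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[component], int(seed)])


@dataclass
class SimulationTruth:
    """Serializable record of what a generator planted.

    ``data`` holds plain values, lists, dicts, Series and DataFrames; the
    JSON round-trip keeps enough to score any recovery experiment without
    re-running the generator.
    """

    component: str
    params: dict = field(default_factory=dict)
    data: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        def enc(v):
            if isinstance(v, pd.DataFrame):
                return {"__frame__": v.to_dict(orient="split")}
            if isinstance(v, pd.Series):
                return {"__series__": {"index": list(v.index),
                                       "values": v.tolist(),
                                       "name": v.name}}
            if isinstance(v, (np.integer,)):
                return int(v)
            if isinstance(v, (np.floating,)):
                return float(v)
            if isinstance(v, OriginationEvent):
                return {"__event__": vars(v)}
            if isinstance(v, dict):
                return {k: enc(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [enc(x) for x in v]
            return v

        text = json.dumps(
            {"component": self.component, "params": enc(self.params),
             "data": enc(self.data)},
            indent=1,
        )
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SimulationTruth":
        text = (Path(source).read_text()
                if isinstance(source, Path) or "\n" not in str(source)
                and Path(str(source)).exists() else str(source))

        def dec(v):
            if isinstance(v, dict):
                if "__frame__" in v:
                    d = v["__frame__"]
                    return pd.DataFrame(
                        d["data"], index=d["index"], columns=d["columns"]
                    )
                if "__series__" in v:
                    d = v["__series__"]
                    return pd.Series(d["values"], index=d["index"],
                                     name=d["name"])
                if "__event__" in v:
                    return OriginationEvent(**v["__event__"])
                return {k: dec(x) for k, x in v.items()}
            if isinstance(v, list):
                return [dec(x) for x in v]
            return v

        raw = json.loads(text)
        return cls(component=raw["component"], params=dec(raw["params"]),
                   data=dec(raw["data"]))


# -- ladder ----------------------------------------------------------------

def simulate_ladder(
    k_strata: int = 12,
    genomes_per_stratum: int | Sequence[int] = 3,
    durations: Sequence[float] | None = None,
    focal: str = "focal_species",
) -> PhylostratumLadder:
    """Build a valid K-rank ladder with synthetic genome ids.

    Rank K holds the focal species alone; every other rank gets
    ``genomes_per_stratum`` genomes named ``psRR_gN``.  Deterministic:
    no randomness is involved.
    """
    if k_strata < 3:
        raise ValueError("a ladder needs at least 3 strata")
    if isinstance(genomes_per_stratum, int):
        counts = [genomes_per_stratum] * (k_strata - 1)
    else:
        counts = list(genomes_per_stratum)
        if len(counts) != k_strata - 1:
            raise ValueError(
                f"need {k_strata - 1} per-stratum genome counts, got {len(counts)}"
            )
    if any(c < 1 for c in counts):
        raise ValueError("every non-focal stratum needs at least one genome")
    if durations is None:
        durations = [10.0] * k_strata
    if len(durations) != k_strata:
        raise ValueError("one duration per stratum required")
    strata = [
        Stratum(
            rank=r,
            label=f"PS{r}",
            genomes=frozenset(
                f"ps{r:02d}_g{j + 1}" for j in range(counts[r - 1])
            ),
            duration_my=float(durations[r - 1]),
        )
        for r in range(1, k_strata)
    ]
    strata.append(
        Stratum(rank=k_strata, label=f"PS{k_strata}",
                genomes=frozenset({focal}),
                duration_my=float(durations[k_strata - 1]))
    )
    return PhylostratumLadder(strata)


# -- homology-hit tables ---------------------------------------------------

def simulate_hit_tables(
    ladder: PhylostratumLadder,
    counts: Mapping[int, int],
    miss_rate: float = 0.0,
    spurious_rate: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Emit homology hits for genes planted at chosen birth strata.

    A gene born at rank b is detectable in its own clade: it leaves one
    hit (e-value well below any sensible cutoff) in every stratum of rank
    b..K-1.  With probability ``miss_rate`` a stratum's hit is dropped
    (BLAST sensitivity failure); with probability ``spurious_rate`` per
    gene one extra hit lands in a uniformly random non-focal stratum
    (spurious similarity).  Truth records each gene's planted birth rank.
    """
    if not 0 <= miss_rate < 1 or not 0 <= spurious_rate < 1:
        raise ValueError("noise rates must lie in [0, 1)")
    bad = [r for r in counts if not 1 <= r <= ladder.max_rank]
    if bad:
        raise ValueError(f"birth rank {bad[0]} outside the ladder")
    rng = _rng(seed, "hits")
    k = ladder.max_rank
    genomes_by_rank = {
        s.rank: sorted(s.genomes) for s in ladder if s.rank < k
    }
    rows = []
    truth_rows = []
    focal = sorted(ladder.focal_genomes)[0]
    for b in sorted(counts):
        for i in range(counts[b]):
            gene = f"g{b:02d}_{i:04d}"
            truth_rows.append((gene, b))
            # every query matches its own genome; dating ignores the
            # self-hit but it keeps hit-less young genes in the table
            rows.append((gene, focal, 1e-180))
            for r in range(b, k):
                if miss_rate and rng.random() < miss_rate:
                    continue
                genome = genomes_by_rank[r][
                    rng.integers(len(genomes_by_rank[r]))
                ]
                ev = 10.0 ** rng.uniform(-60.0, -10.0)
                rows.append((gene, genome, ev))
            if spurious_rate and rng.random() < spurious_rate:
                r = int(rng.integers(1, k))
                genome = genomes_by_rank[r][
                    rng.integers(len(genomes_by_rank[r]))
                ]
                rows.append((gene, genome, 10.0 ** rng.uniform(-30.0, -10.0)))
    hits = pd.DataFrame(rows, columns=["query", "subject_genome", "evalue"])
    hits["bitscore"] = -np.log10(hits["evalue"]) * 2.0 if len(hits) else 0.0
    hits["program"] = "blastp"
    truth = SimulationTruth(
        component="hits",
        params={"counts": {int(r): int(n) for r, n in counts.items()},
                "miss_rate": miss_rate, "spurious_rate": spurious_rate,
                "seed": seed},
        data={"birth_rank": pd.Series(
            dict(truth_rows), name="birth_rank").sort_index()},
    )
    return hits, truth


# -- de novo loci ----------------------------------------------------------

@dataclass
class DenovoLocus:
    """One synthetic locus: coding ingroup, lesioned outgroup, truth."""

    id: str
    query: CodingGene
    ingroup: dict[str, str]
    outgroup: dict[str, str]
    events: dict[str, list[OriginationEvent]]  # planted, per outgroup species

    @property
    def is_de_novo(self) -> bool:
        return any(self.events.values())


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    stop = ("TAA", "TAG", "TGA")[rng.integers(3)]
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + stop


def _codon_index(pos: int) -> int:
    return pos // 3


def _creates_stop(seq: str, pos: int, base: str) -> bool:
    c = _codon_index(pos)
    codon = seq[3 * c:3 * c + 3]
    mutated = codon[:pos - 3 * c] + base + codon[pos - 3 * c + 1:]
    return mutated in STOP_CODONS


def _choose_stop(rng, seq: str, protected: set[int]):
    """Pick a single-base change turning an internal codon into a stop.

    Positions are query coordinates; the returned event converts the
    ancestral (stop-carrying) state back into the query state.
    """
    n_codons = len(seq) // 3
    order = rng.permutation(np.arange(2, n_codons - 2))
    for c in order:
        if c in protected:
            continue
        codon = seq[3 * c:3 * c + 3]
        choices = []
        for k in range(3):
            for b in _BASES:
                if b != codon[k] and codon[:k] + b + codon[k + 1:] in STOP_CODONS:
                    choices.append((k, b))
        if not choices:
            continue
        k, b = choices[rng.integers(len(choices))]
        pos = 3 * c + k
        ev = OriginationEvent(kind="substitution", position=pos + 1,
                              ancestral=b, derived=seq[pos],
                              resolves="premature_stop")
        return ev, {c}
    raise RuntimeError("no codon available for a stop lesion")


def _choose_start_loss(rng, seq: str):
    k = int(rng.integers(3))
    b = rng.choice([x for x in _BASES if x != seq[k]])
    ev = OriginationEvent(kind="substitution", position=k + 1,
                          ancestral=b, derived=seq[k],
                          resolves="missing_start")
    return ev, {0}


def _choose_frameshift(rng, seq: str, protected: set[int]):
    """Pick a mod-3 != 0 indel whose optimal gap placement is unambiguous."""
    length = int(rng.choice([1, 2, 4, 5]))
    insert = bool(rng.integers(2))
    for _ in range(200):
        pos = int(rng.integers(9, len(seq) - 9 - length))
        if any(_codon_index(p) in protected
               for p in range(pos - 1, pos + length + 1)):
            continue
        if insert:
            frag = "".join(rng.choice(list(_BASES), size=length))
            # forbid slippage: fragment ends must differ from the flanks
            if frag[0] == seq[pos] or frag[-1] == seq[pos - 1]:
                continue
            ev = OriginationEvent(kind="deletion", position=pos + 1,
                                  ancestral=frag, derived="",
                                  resolves="frameshift_indel")
        else:
            frag = seq[pos:pos + length]
            if frag[0] == seq[pos + length] or frag[-1] == seq[pos - 1]:
                continue
            ev = OriginationEvent(kind="insertion", position=pos + 1,
                                  ancestral="", derived=frag,
                                  resolves="frameshift_indel")
        touched = {_codon_index(p) for p in range(pos - 1, pos + length + 1)}
        return ev, touched
    raise RuntimeError("could not place an unambiguous frameshift")


def _apply_inverse_events(seq: str, events: list[OriginationEvent]) -> str:
    """Derive the ancestral (outgroup) state by undoing enabling events.

    Events carry 1-based query positions; applying right-to-left keeps
    every remaining position valid while the string changes length.
    """
    out = seq
    for ev in sorted(events, key=lambda e: -e.position):
        p = ev.position - 1
        if ev.kind == "substitution":
            assert out[p] == ev.derived
            out = out[:p] + ev.ancestral + out[p + 1:]
        elif ev.kind == "deletion":
            # enabling event deletes ancestral bases -> ancestor had them
            out = out[:p] + ev.ancestral + out[p:]
        else:  # insertion: enabling event inserted query bases
            assert out[p:p + len(ev.derived)] == ev.derived
            out = out[:p] + out[p + len(ev.derived):]
    return out


def _background_substitutions(rng, seq: str, rate: float,
                              protected: set[int]) -> str:
    """Neutral divergence that never introduces an in-frame stop, never
    touches protected codons nor the start / terminal stop codons."""
    out = list(seq)
    n = len(seq)
    k_subs = rng.binomial(n, rate)
    positions = rng.choice(n, size=min(k_subs, n), replace=False)
    for pos in positions:
        c = _codon_index(int(pos))
        if c in protected or c == 0 or c == n // 3 - 1:
            continue
        base = rng.choice([b for b in _BASES if b != out[pos]])
        if not _creates_stop("".join(out), int(pos), base):
            out[pos] = base
    return "".join(out)


def simulate_denovo_loci(
    n_loci: int,
    lesion_mix: Mapping[str, float] | None = None,
    events_per_locus: tuple[int, int] = (1, 1),
    n_ingroup: int = 2,
    n_outgroup: int = 4,
    min_lesioned_outgroups: int = 1,
    background_divergence: float = 0.02,
    length_range: tuple[int, int] = (150, 900),
    seed: int = 0,
) -> tuple[list[DenovoLocus], SimulationTruth]:
    """Generate orthologous regions around planted de novo ORFs.

    Each locus gets a random valid ORF (ingroup species carry it intact,
    with light synonymous divergence for the non-focal ingroup species).
    Outgroup sequences are derived by applying the inverse of the planted
    enabling events — a premature stop by substitution, a frameshift by a
    mod-3 != 0 indel, or a destroyed start codon — plus neutral background
    substitutions (rate ``background_divergence``) that are constrained
    never to create additional lesions.  Set ``events_per_locus=(0, 0)``
    for negative-control loci that are intact everywhere.

    Truth records, per locus and outgroup species, the exact enabling
    events (1-based query positions, ancestral and derived alleles) that
    :func:`bambusa.denovo.reconstruct_origination` should recover.
    """
    if n_loci < 1:
        raise ValueError("need at least one locus")
    if lesion_mix is None:
        lesion_mix = {"premature_stop": 0.4, "frameshift_indel": 0.4,
                      "missing_start": 0.2}
    kinds = sorted(lesion_mix)
    weights = np.array([lesion_mix[k] for k in kinds], dtype=float)
    weights /= weights.sum()
    rng = _rng(seed, "denovo")
    lo, hi = length_range
    loci: list[DenovoLocus] = []
    for li in range(n_loci):
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        cds = _random_orf(rng, n_codons)
        query = CodingGene(id=f"locus{li:03d}", cds=cds)
        ingroup = {"ingroup_sp1": cds}
        for j in range(1, n_ingroup):
            ingroup[f"ingroup_sp{j + 1}"] = _background_substitutions(
                rng, cds, background_divergence / 2, protected=set()
            )
        outgroup: dict[str, str] = {}
        events: dict[str, list[OriginationEvent]] = {}
        n_events = int(rng.integers(events_per_locus[0],
                                    events_per_locus[1] + 1))
        lesioned = rng.permutation(n_outgroup)[:min_lesioned_outgroups]
        for j in range(n_outgroup):
            sp = f"outgroup_sp{j + 1}"
            evs: list[OriginationEvent] = []
            protected: set[int] = set()
            if j in lesioned and n_events > 0:
                start_used = False
                # all events are chosen in query coordinates first, on
                # disjoint codon neighbourhoods, then applied at once
                for _ in range(n_events):
                    kind = kinds[int(rng.choice(len(kinds), p=weights))]
                    if kind == "missing_start" and start_used:
                        kind = "premature_stop"
                    if kind == "premature_stop":
                        ev, touched = _choose_stop(rng, cds, protected)
                    elif kind == "missing_start":
                        ev, touched = _choose_start_loss(rng, cds)
                        start_used = True
                    else:
                        ev, touched = _choose_frameshift(rng, cds, protected)
                    protected |= touched
                    evs.append(ev)
            seq = _apply_inverse_events(cds, evs)
            if background_divergence > 0 and not any(
                e.kind in ("insertion", "deletion") for e in evs
            ):
                # indel-free ancestors keep query coordinates, so neutral
                # divergence can be layered on without moving gap anchors
                seq = _background_substitutions(
                    rng, seq, background_divergence, protected
                )
            outgroup[sp] = seq
            events[sp] = sorted(evs, key=lambda e: e.position)
        loci.append(DenovoLocus(id=query.id, query=query, ingroup=ingroup,
                                outgroup=outgroup, events=events))
    truth = SimulationTruth(
        component="denovo",
        params={"n_loci": n_loci, "lesion_mix": dict(lesion_mix),
                "events_per_locus": list(events_per_locus), "seed": seed},
        data={
            "events": {
                loc.id: {sp: list(evs) for sp, evs in loc.events.items()}
                for loc in loci
            },
            "is_de_novo": {loc.id: loc.is_de_novo for loc in loci},
        },
    )
    return loci, truth


# -- expression ------------------------------------------------------------

def simulate_expression(
    ages: pd.Series,
    tissues: Sequence[str] = (
        "root", "leaf", "rhizome_tip", "lateral_bud", "shoot_tip",
        "inflorescence",
    ),
    multi_stage_tissue: str = "shoot",
    n_stages: int = 8,
    peak_stages: Sequence[int] = (3, 4),
    young_bias_effect: float = 1.0,
    young_ranks: Sequence[int] | None = None,
    n_seg_per_tissue: int = 0,
    sigma: float = 1.0,
    within_sigma: float = 0.5,
    baseline_median: float = 5.0,
    seg_dominance_factor: float = 50.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str], SimulationTruth]:
    """FPKM matrix with planted age-biased and tissue-specific expression.

    Per-gene baseline levels are log-normal across genes (median
    ``baseline_median`` FPKM, log-sd ``sigma``); around its baseline each
    gene varies log-normally across samples with log-sd ``within_sigma``
    (default 0.5, i.e. roughly two- to three-fold cross-tissue variation,
    the regime of broadly expressed genes — unplanted genes are meant to
    be non-specific).  Columns are one per single-stage tissue plus
    ``n_stages`` stage columns for the multi-stage tissue.  Genes of the
    ``young_ranks`` strata (default: the two youngest present) are
    multiplied by ``young_bias_effect`` in the designated peak stages —
    ``young_bias_effect=1`` is the null.  ``n_seg_per_tissue`` genes per
    tissue are made specifically expressed by boosting their target tissue
    ``seg_dominance_factor``-fold and suppressing the rest.

    Returns (matrix, tissue_map, truth); truth records peak stages, the
    biased gene set and the SEG assignment.
    """
    if young_bias_effect < 1:
        raise ValueError("effect sizes below 1 are not supported")
    rng = _rng(seed, "expression")
    genes = list(ages.index)
    if multi_stage_tissue in tissues:
        raise ValueError("multi-stage tissue must not repeat in tissues")
    stage_cols = [f"{multi_stage_tissue}_S{i + 1}" for i in range(n_stages)]
    columns = list(tissues) + stage_cols
    tissue_map = {c: c for c in tissues}
    tissue_map.update({c: multi_stage_tissue for c in stage_cols})

    base = np.exp(rng.normal(math.log(baseline_median), sigma,
                             size=(len(genes), 1)))
    noise = np.exp(rng.normal(0.0, within_sigma,
                              size=(len(genes), len(columns))))
    expr = pd.DataFrame(base * noise, index=pd.Index(genes, name="gene"),
                        columns=columns)

    if young_ranks is None:
        present = sorted(ages.unique())
        young_ranks = present[-2:]
    young = ages.index[ages.isin(list(young_ranks))]
    peak_cols = [stage_cols[i] for i in peak_stages]
    expr.loc[young, peak_cols] *= young_bias_effect

    seg_truth: dict[str, str] = {}
    if n_seg_per_tissue > 0:
        all_tissues = list(tissues) + [multi_stage_tissue]
        pool = rng.permutation(np.array(genes, dtype=object))
        need = n_seg_per_tissue * len(all_tissues)
        if need > len(pool):
            raise ValueError("not enough genes to plant that many SEGs")
        chosen = pool[:need]
        for t_i, tissue in enumerate(all_tissues):
            sel = chosen[t_i * n_seg_per_tissue:(t_i + 1) * n_seg_per_tissue]
            target_cols = ([tissue] if tissue in tissues else stage_cols)
            other_cols = [c for c in columns if c not in target_cols]
            expr.loc[sel, target_cols] = (
                expr.loc[sel, target_cols] * seg_dominance_factor
            ).clip(lower=5.0)
            expr.loc[sel, other_cols] *= 0.002
            for g in sel:
                seg_truth[g] = tissue

    truth = SimulationTruth(
        component="expression",
        params={"young_bias_effect": young_bias_effect,
                "peak_stages": list(peak_stages), "sigma": sigma,
                "n_seg_per_tissue": n_seg_per_tissue, "seed": seed},
        data={
            "peak_columns": peak_cols,
            "young_ranks": [int(r) for r in young_ranks],
            "biased_genes": sorted(young),
            "seg": pd.Series(seg_truth, name="seg_tissue", dtype=object),
        },
    )
    return expr, tissue_map, truth


# -- divergence ------------------------------------------------------------

def _site_counts(cds: str) -> tuple[float, float]:
    s = n = 0.0
    for i in range(0, len(cds) - 3, 3):  # skip the terminal stop
        cs, cn = _codon_sites(cds[i:i + 3])
        s += cs
        n += cn
    return s, n


def _syn_neighbors(codon: str) -> list[tuple[int, str]]:
    from .kaks import _aa
    out = []
    for k in range(3):
        for b in "ACGT":
            alt = codon[:k] + b + codon[k + 1:]
            if b != codon[k] and alt not in STOP_CODONS and _aa(alt) == _aa(codon):
                out.append((k, b))
    return out


def _nonsyn_neighbors(codon: str) -> list[tuple[int, str]]:
    from .kaks import _aa
    out = []
    for k in range(3):
        for b in "ACGT":
            alt = codon[:k] + b + codon[k + 1:]
            if b != codon[k] and alt not in STOP_CODONS and _aa(alt) != _aa(codon):
                out.append((k, b))
    return out


def simulate_divergence(
    ages: pd.Series,
    omega_by_rank: Mapping[int, float],
    ks: float = 0.3,
    n_codons: int = 300,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, tuple[str, str]], SimulationTruth]:
    """Evolve a CDS pair per gene under a planted omega at a given Ks.

    For each gene a random ancestor ORF of ``n_codons`` codons is drawn;
    the derived copy receives synonymous and nonsynonymous substitutions
    whose expected numbers match the planted (Ks, omega = Ka/Ks) after
    Jukes-Cantor: at most one change per codon, never creating a stop.
    Truth records the planted omega per gene; the returned frame carries
    the planted Ka/Ks and the divergence vector consumed by the TDI.
    """
    missing = sorted(set(ages.unique()) - set(omega_by_rank))
    if missing:
        raise KeyError(f"no omega scheduled for rank {missing[0]}")
    rng = _rng(seed, "divergence")
    pairs: dict[str, tuple[str, str]] = {}
    rows = []
    for gene, rank in ages.items():
        omega = float(omega_by_rank[int(rank)])
        cds = _random_orf(rng, n_codons)
        s_sites, n_sites = _site_counts(cds)
        ps = 0.75 * (1.0 - math.exp(-4.0 * ks / 3.0))
        pa = 0.75 * (1.0 - math.exp(-4.0 * omega * ks / 3.0))
        # counts are planted at their expectations (placement is random):
        # the pair's divergence matches the scheduled (Ks, omega) contract
        m_syn = int(round(ps * s_sites))
        m_non = int(round(pa * n_sites))
        derived = list(cds)
        codon_order = rng.permutation(np.arange(1, n_codons - 1))
        ci = 0
        for want_syn, m in ((True, m_syn), (False, m_non)):
            placed = 0
            while placed < m and ci < len(codon_order):
                c = int(codon_order[ci])
                ci += 1
                codon = "".join(derived[3 * c:3 * c + 3])
                nb = (_syn_neighbors(codon) if want_syn
                      else _nonsyn_neighbors(codon))
                if not nb:
                    continue
                k, b = nb[rng.integers(len(nb))]
                derived[3 * c + k] = b
                placed += 1
        pairs[gene] = (cds, "".join(derived))
        rows.append((gene, int(rank), omega, ks))
    frame = pd.DataFrame(
        rows, columns=["gene", "rank", "omega_true", "ks_target"]
    ).set_index("gene")
    truth = SimulationTruth(
        component="divergence",
        params={"omega_by_rank": {int(r): float(w)
                                  for r, w in omega_by_rank.items()},
                "ks": ks, "n_codons": n_codons, "seed": seed},
        data={"omega_true": frame["omega_true"]},
    )
    return frame, pairs, truth
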