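"""De novo gene-birth detection and origination-event reconstruction.

A de novo gene candidate is an ORF that is intact in the ingroup species
but demonstrably noncoding in at least one outgroup: its orthologous
sequence carries ORF-disabling lesions (premature stop codons,
frameshifting indels, a destroyed start codon).  Given cross-species
orthologous regions, this module filters homology hits, confirms
orthology reciprocally, diagnoses coding status in the query's reading
frame, reconstructs the minimal enabling mutations (substitutions or
indels) that turned the noncoding ancestor into the coding gene, and
classifies the origination mechanism.

Coordinates are 0-based half-open internally; reported origination events
carry the 1-based "at N bp" position convention used in the field's
figures (``OriginationEvent.position`` is 1-based).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import Align

__all__ = [
    "CodingGene",
    "RegionHit",
    "Lesion",
    "OriginationEvent",
    "EffectiveHits",
    "filter_effective_hits",
    "reciprocal_confirm",
    "align_to_orf",
    "diagnose_coding_status",
    "classify_de_novo",
    "reconstruct_origination",
    "classify_mechanism",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CodingGene:
    """An intact protein-coding ORF: ATG .. stop, no internal stop."""

    id: str
    cds: str

    def __post_init__(self):
        cds = self.cds.upper()
        object.__setattr__(self, "cds", cds)
        if len(cds) % 3:
            raise ValueError(f"{self.id}: CDS length not a multiple of 3")
        if len(cds) < 6:
            raise ValueError(f"{self.id}: CDS too short")
        if not cds.startswith("ATG"):
            raise ValueError(f"{self.id}: CDS does not begin with ATG")
        if cds[-3:] not in STOP_CODONS:
            raise ValueError(f"{self.id}: CDS does not end with a stop codon")
        internal = [
            i for i in range(0, len(cds) - 3, 3) if cds[i:i + 3] in STOP_CODONS
        ]
        if internal:
            raise ValueError(
                f"{self.id}: internal stop codon at nt {internal[0]}"
            )

    def __len__(self) -> int:
        return len(self.cds)


@dataclass(frozen=True)
class RegionHit:
    """One nucleotide-level hit of a query ORF against a target genome."""

    query: str
    target_genome: str
    query_start: int  # 0-based half-open on the ORF
    query_end: int
    target_start: int
    target_end: int
    strand: str = "+"
    identity: float = 100.0
    matches: int | None = None  # matched bases; defaults to query span

    def __post_init__(self):
        if not 0 <= self.query_start < self.query_end:
            raise ValueError("invalid query span")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity must lie in [0, 100]")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")

    @property
    def matched_length(self) -> int:
        return (self.matches if self.matches is not None
                else self.query_end - self.query_start)


@dataclass
class EffectiveHits:
    """Accepted hits per target genome plus the eligibility verdict."""

    accepted: dict[str, list[RegionHit]]
    ineligible_genomes: set[str] = field(default_factory=set)

    @property
    def eligible(self) -> bool:
        """False when any genome holds more than one effective hit."""
        return not self.ineligible_genomes

    def single_hits(self) -> dict[str, RegionHit]:
        return {g: hs[0] for g, hs in self.accepted.items() if len(hs) == 1}


def filter_effective_hits(
    hits: Iterable[RegionHit],
    query: CodingGene,
    min_identity: float = 80.0,
    min_coverage: float = 0.20,
) -> EffectiveHits:
    """Keep effective hits: identity and ORF coverage above the floors.

    A hit is effective when its identity is at least ``min_identity`` and
    its matched bases cover at least ``min_coverage`` of the query ORF
    (inclusive boundaries).  A genome with two or more effective hits has
    no unambiguous ortholog; such genomes mark the query ineligible.
    """
    accepted: dict[str, list[RegionHit]] = {}
    orf_len = len(query)
    for h in hits:
        if h.query != query.id:
            raise ValueError(f"hit query {h.query!r} != ORF {query.id!r}")
        if h.identity >= min_identity and h.matched_length >= min_coverage * orf_len:
            accepted.setdefault(h.target_genome, []).append(h)
    bad = {g for g, hs in accepted.items() if len(hs) > 1}
    return EffectiveHits(accepted=accepted, ineligible_genomes=bad)


# -- pairwise alignment ----------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    """Global affine-gap aligner: match 2, mismatch -3, open -5, extend -2."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


_ALIGNER = _make_aligner()


def align_to_orf(query_cds: str, ortholog: str) -> tuple[str, str]:
    """Globally align an orthologous region to a query ORF.

    Returns the gapped (query, ortholog) strings.  The first optimal
    alignment is taken; Biopython's traceback order makes this
    deterministic for fixed inputs.
    """
    aln = _ALIGNER.align(query_cds.upper(), ortholog.upper())[0]
    return str(aln[0]), str(aln[1])


def reciprocal_confirm(
    ortholog: str,
    query_orfs: Sequence[CodingGene],
    originating: str,
) -> bool:
    """Best-reciprocal check: the ortholog must align back to its ORF.

    The orthologous region is aligned against every query ORF; it is
    confirmed only when the originating ORF scores strictly best (a tie
    with a paralog is not confirmation).
    """
    if not query_orfs:
        return False
    scores = {
        orf.id: _ALIGNER.score(orf.cds, ortholog.upper())
        for orf in query_orfs
    }
    if originating not in scores:
        raise KeyError(f"originating ORF {originating!r} not among queries")
    best = max(scores.values())
    winners = [gid for gid, s in scores.items() if s == best]
    return winners == [originating]


# -- coding-status diagnosis ----------------------------------------------

@dataclass(frozen=True)
class Lesion:
    """An ORF-disabling defect of an orthologous sequence.

    ``position`` is 0-based in query-ORF nucleotide coordinates.  For
    frameshifts ``length`` is the indel length (mod 3 != 0) and ``inserted``
    tells whether the ortholog carries extra bases (True) or lacks query
    bases (False).
    """

    kind: str  # premature_stop | frameshift_indel | missing_start
    position: int
    detail: str = ""
    length: int = 0
    inserted: bool = False

    def __post_init__(self):
        if self.kind not in (
            "premature_stop", "frameshift_indel", "missing_start"
        ):
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if self.kind == "frameshift_indel" and self.length % 3 == 0:
            raise ValueError("frameshift indel length must not be 0 mod 3")


def _column_map(qa: str, oa: str):
    """Per-column bookkeeping of a gapped (query, ortholog) pair.

    Returns (ortho_at_q, columns_of_q, insertion_runs, deletion_runs) where
    ``ortho_at_q[i]`` is the ortholog character aligned to query position
    i ('-' when deleted), ``columns_of_q[i]`` the alignment column of
    query position i, and runs are (query_position, length, columns) gap
    runs strictly inside the aligned span (terminal overhangs are treated
    as missing sequence, not indels).
    """
    assert len(qa) == len(oa)
    ortho_at_q: list[str] = []
    col_of_q: list[int] = []
    ins_runs: list[tuple[int, int, list[int]]] = []
    del_runs: list[tuple[int, int, list[int]]] = []
    qpos = 0
    run_kind = None
    run_cols: list[int] = []
    run_qpos = 0

    # span of columns where the ortholog actually has sequence
    o_cols = [i for i, ch in enumerate(oa) if ch != "-"]
    o_lo = o_cols[0] if o_cols else 0
    o_hi = o_cols[-1] if o_cols else -1
    q_cols = [i for i, ch in enumerate(qa) if ch != "-"]
    q_lo = q_cols[0] if q_cols else 0
    q_hi = q_cols[-1] if q_cols else -1

    def close_run():
        nonlocal run_kind, run_cols
        if run_kind == "ins":
            ins_runs.append((run_qpos, len(run_cols), run_cols))
        elif run_kind == "del":
            del_runs.append((run_qpos, len(run_cols), run_cols))
        run_kind, run_cols = None, []

    for i, (qc, oc) in enumerate(zip(qa, oa)):
        inside_o = o_lo <= i <= o_hi
        inside_q = q_lo <= i <= q_hi
        if qc != "-" and oc != "-":
            close_run()
            ortho_at_q.append(oc)
            col_of_q.append(i)
            qpos += 1
        elif qc == "-" and oc != "-":
            # ortholog insertion relative to the query frame
            if inside_q:
                if run_kind != "ins":
                    close_run()
                    run_kind, run_qpos = "ins", qpos
                run_cols.append(i)
        elif qc != "-" and oc == "-":
            ortho_at_q.append("-")
            col_of_q.append(i)
            if inside_o:
                if run_kind != "del":
                    close_run()
                    run_kind, run_qpos = "del", qpos
                run_cols.append(i)
            qpos += 1
    close_run()
    return "".join(ortho_at_q), col_of_q, ins_runs, del_runs


def diagnose_coding_status(
    query: CodingGene,
    ortholog: str | None = None,
    aligned: tuple[str, str] | None = None,
) -> tuple[str, list[Lesion]]:
    """Read an orthologous sequence in the query ORF's frame.

    Either a raw ``ortholog`` sequence (aligned internally) or a
    pre-computed gapped ``aligned`` pair may be given.  Reports every
    in-frame stop codon before the terminal codon, every internal gap run
    whose length is not a multiple of three (frameshift), and a
    non-``ATG`` aligned start.  Status is ``"intact"`` with no lesions,
    ``"disabled"`` otherwise, and ``"absent"`` when fewer than one codon
    aligns at all.
    """
    if aligned is None:
        if ortholog is None:
            raise ValueError("give either an ortholog sequence or an alignment")
        if not ortholog or len(ortholog.replace("-", "")) < 3:
            return "absent", []
        aligned = align_to_orf(query.cds, ortholog)
    qa, oa = aligned
    if qa.replace("-", "") != query.cds:
        raise ValueError("aligned query row does not match the ORF")
    ortho_at_q, _, ins_runs, del_runs = _column_map(qa, oa)
    aligned_bases = sum(
        1 for q, o in zip(ortho_at_q, query.cds) if o != "-"
    )
    if aligned_bases < 3:
        return "absent", []

    lesions: list[Lesion] = []
    start = ortho_at_q[0:3]
    if "-" in start or start != "ATG":
        lesions.append(
            Lesion(kind="missing_start", position=0, detail=start)
        )
    n = len(query.cds)
    for p in range(0, n - 3, 3):  # exclude the terminal codon
        triplet = ortho_at_q[p:p + 3]
        if "-" not in triplet and triplet in STOP_CODONS:
            lesions.append(
                Lesion(kind="premature_stop", position=p, detail=triplet)
            )
    for qpos, length, _cols in ins_runs:
        if length % 3:
            lesions.append(
                Lesion(kind="frameshift_indel", position=qpos,
                       detail=f"+{length}", length=length, inserted=True)
            )
    for qpos, length, _cols in del_runs:
        if length % 3:
            lesions.append(
                Lesion(kind="frameshift_indel", position=qpos,
                       detail=f"-{length}", length=length, inserted=False)
            )
    lesions.sort(key=lambda l: (l.position, l.kind))
    return ("intact" if not lesions else "disabled"), lesions


def classify_de_novo(
    statuses: Mapping[str, str],
    ingroup: Iterable[str],
    outgroup: Iterable[str],
) -> str:
    """Candidate verdict from per-species coding statuses.

    ``"candidate"`` when every ingroup species with a confirmed region is
    intact and at least one outgroup region is disabled; species whose
    region is absent do not veto.  With no outgroup region at all the
    verdict is ``"indeterminate"``.
    """
    ingroup = list(ingroup)
    outgroup = list(outgroup)
    unknown = set(statuses) - set(ingroup) - set(outgroup)
    if unknown:
        raise KeyError(f"species {sorted(unknown)[0]!r} in neither group")
    in_present = [statuses[s] for s in ingroup
                  if statuses.get(s, "absent") != "absent"]
    out_present = [statuses[s] for s in outgroup
                   if statuses.get(s, "absent") != "absent"]
    if not out_present:
        return "indeterminate"
    if in_present and all(s == "intact" for s in in_present) and any(
        s == "disabled" for s in out_present
    ):
        return "candidate"
    return "not_candidate"


# -- origination reconstruction -------------------------------------------

@dataclass(frozen=True)
class OriginationEvent:
    """A minimal enabling mutation on the path from noncoding to coding.

    ``position`` follows the 1-based "at N bp" reporting convention of the
    query ORF (internal computation is 0-based; this field is already
    converted).  ``ancestral``/``derived`` hold the outgroup and query
    alleles ('' for the absent side of an indel).
    """

    kind: str  # substitution | insertion | deletion
    position: int
    ancestral: str
    derived: str
    resolves: str  # lesion kind this event removes

    def __post_init__(self):
        if self.kind not in ("substitution", "insertion", "deletion"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.position < 1:
            raise ValueError("event positions are 1-based")


def reconstruct_origination(
    query: CodingGene,
    ortholog: str | None = None,
    aligned: tuple[str, str] | None = None,
    max_rounds: int = 10,
) -> tuple[list[OriginationEvent], list[Lesion]]:
    """Infer the enabling mutations that created the query ORF.

    For each diagnosed lesion the minimal edit moving the outgroup state
    to the query state is emitted: substitutions for stop/start codon
    differences, the indel itself for frameshifts.  Events are applied to
    the (aligned) ancestral sequence and the diagnosis repeated, so chains
    of lesions (e.g. a frameshift masking a downstream stop) resolve over
    successive rounds; the round-trip guarantee is that applying all
    returned events leaves a lesion-free frame within the aligned span.

    Returns ``(events, unresolved)`` where ``unresolved`` lists lesions
    that could not be repaired by comparison with the query (e.g. the
    region is absent); in that case ``events`` may be incomplete.
    """
    if aligned is None:
        if ortholog is None:
            raise ValueError("give either an ortholog sequence or an alignment")
        status, _ = diagnose_coding_status(query, ortholog=ortholog)
        if status == "absent":
            return [], []
        aligned = align_to_orf(query.cds, ortholog)
    qa = list(aligned[0])
    oa = list(aligned[1])
    events: list[OriginationEvent] = []

    for _ in range(max_rounds):
        status, lesions = diagnose_coding_status(
            query, aligned=("".join(qa), "".join(oa))
        )
        if status != "disabled":
            break
        ortho_at_q, col_of_q, ins_runs, del_runs = _column_map(
            "".join(qa), "".join(oa)
        )
        progressed = False
        for les in lesions:
            if les.kind in ("premature_stop", "missing_start"):
                p = les.position
                for k in range(3):
                    oc = ortho_at_q[p + k]
                    qc = query.cds[p + k]
                    if oc not in ("-", qc):
                        events.append(OriginationEvent(
                            kind="substitution", position=p + k + 1,
                            ancestral=oc, derived=qc, resolves=les.kind,
                        ))
                        oa[col_of_q[p + k]] = qc
                        progressed = True
            elif les.kind == "frameshift_indel":
                if les.inserted:
                    run = next(r for r in ins_runs
                               if r[0] == les.position and r[1] == les.length)
                    bases = "".join(oa[c] for c in run[2])
                    events.append(OriginationEvent(
                        kind="deletion", position=les.position + 1,
                        ancestral=bases, derived="", resolves=les.kind,
                    ))
                    for c in run[2]:
                        oa[c] = "-"
                else:
                    run = next(r for r in del_runs
                               if r[0] == les.position and r[1] == les.length)
                    bases = "".join(qa[c] for c in run[2])
                    events.append(OriginationEvent(
                        kind="insertion", position=les.position + 1,
                        ancestral="", derived=bases, resolves=les.kind,
                    ))
                    for c in run[2]:
                        oa[c] = qa[c]
                progressed = True
        if not progressed:
            break

    status, remaining = diagnose_coding_status(
        query, aligned=("".join(qa), "".join(oa))
    )
    events.sort(key=lambda e: e.position)
    return events, (remaining if status == "disabled" else [])


def classify_mechanism(events: Sequence[OriginationEvent]) -> str:
    """Mechanism label from an event list: substitution, indel or mixed."""
    if not events:
        raise ValueError("cannot classify an empty event list")
    kinds = {
        "substitution" if e.kind == "substitution" else "indel"
        for e in events
    }
    return kinds.pop() if len(kinds) == 1 else "mixed"
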