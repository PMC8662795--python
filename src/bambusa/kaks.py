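"""Pairwise Ka/Ks estimation by the Nei-Gojobori (NG86) counting method.

Synonymous and nonsynonymous sites are counted per codon (mutations to
stop codons count as nonsynonymous, so every codon carries exactly three
sites) and averaged over the two sequences.  Codons differing at more than
one position are resolved by averaging the synonymous/nonsynonymous step
counts over all minimal mutational pathways, excluding pathways that pass
through a stop codon.  Raw proportions are corrected for multiple hits
with the Jukes-Cantor formula.  Significance of deviation from neutral
evolution (omega = 1) is assessed by a chi-square test on the observed
substitution counts against their expectation under equal per-site rates.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from functools import lru_cache

from scipy.stats import chi2

__all__ = ["KaKsResult", "kaks_ng86", "selection_test"]

_BASES = "TCAG"
_STOPS = frozenset({"TAA", "TAG", "TGA"})

# standard nuclear genetic code
_CODE = {
    a + b + c: aa
    for a, b, c, aa in zip(
        *(
            [x for x in "TTTTTTTTTTTTTTTTCCCCCCCCCCCCCCCCAAAAAAAAAAAAAAAAGGGGGGGGGGGGGGGG"],
            [x for x in "TTTTCCCCAAAAGGGG" * 4],
            [x for x in "TCAG" * 16],
            [x for x in
             "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"],
        )
    )
}


def _aa(codon: str) -> str:
    return _CODE[codon]


@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Each position contributes its fraction of synonymous one-step changes;
    changes into a stop codon are nonsynonymous, so the two counts always
    sum to 3.
    """
    aa = _aa(codon)
    syn = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in _STOPS and _aa(alt) == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _codon_path_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) substitution counts between two codons.

    Averages over all orderings of the differing positions; pathways whose
    intermediate codons are stops are excluded.  If every pathway is
    blocked the average falls back to all pathways with stop-passing steps
    scored as nonsynonymous.
    """
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in itertools.permutations(diffs):
        cur = c1
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOPS and nxt != c2:
                through_stop = True
            if cur in _STOPS or nxt in _STOPS:
                nd += 1  # change touching a stop cannot be synonymous
            elif _aa(cur) == _aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if through_stop else valid).append((sd, nd))
    paths = valid if valid else blocked
    s = sum(p[0] for p in paths) / len(paths)
    n = sum(p[1] for p in paths) / len(paths)
    return s, n


def _jukes_cantor(p: float) -> float:
    """Jukes-Cantor distance; NaN when the proportion is saturated."""
    if p < 0:
        raise ValueError("negative proportion")
    if p == 0:
        return 0.0
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class KaKsResult:
    """NG86 estimates for one sequence pair.

    ``omega`` is NaN when Ks is zero or saturated.  ``s_subs`` / ``n_subs``
    are the (pathway-averaged) numbers of synonymous / nonsynonymous
    substitutions; ``s_sites`` / ``n_sites`` the corresponding site counts.
    ``p_value`` and ``selection`` are filled by :func:`selection_test`.
    """

    ka: float
    ks: float
    omega: float
    s_sites: float
    n_sites: float
    s_subs: float
    n_subs: float
    n_codons: int
    p_value: float = math.nan
    selection: str = "untested"
    low_power: bool = False


def kaks_ng86(cds_a: str, cds_b: str) -> KaKsResult:
    """Estimate Ka, Ks and omega for an in-frame codon alignment.

    Sequences must be equal length, gap-free and a multiple of three.
    A shared terminal stop codon is ignored; codons containing ambiguous
    bases (anything outside ACGT) in either sequence are skipped.
    """
    a = cds_a.upper().replace("U", "T")
    b = cds_b.upper().replace("U", "T")
    if len(a) != len(b):
        raise ValueError("sequences differ in length; align and strip gaps")
    if len(a) % 3 or not a:
        raise ValueError("alignment length must be a positive multiple of 3")
    if "-" in a or "-" in b:
        raise ValueError("gaps present; strip gap columns first")

    codons = [(a[i:i + 3], b[i:i + 3]) for i in range(0, len(a), 3)]
    if codons and codons[-1][0] in _STOPS and codons[-1][1] in _STOPS:
        codons = codons[:-1]

    s_sites = n_sites = 0.0
    s_subs = n_subs = 0.0
    used = 0
    for ca, cb in codons:
        if any(ch not in "ACGT" for ch in ca + cb):
            continue  # ambiguity codes: skip the whole codon
        if ca in _STOPS or cb in _STOPS:
            raise ValueError(f"internal stop codon in alignment: {ca}/{cb}")
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        s_sites += (sa + sb) / 2.0
        n_sites += (na + nb) / 2.0
        sd, nd = _codon_path_counts(ca, cb)
        s_subs += sd
        n_subs += nd
        used += 1
    if used == 0:
        raise ValueError("no usable codons")

    ps = s_subs / s_sites if s_sites > 0 else math.nan
    pn = n_subs / n_sites if n_sites > 0 else math.nan
    ks = _jukes_cantor(ps) if not math.isnan(ps) else math.nan
    ka = _jukes_cantor(pn) if not math.isnan(pn) else math.nan
    omega = ka / ks if ks and ks > 0 and not math.isnan(ka) else math.nan
    return KaKsResult(
        ka=ka, ks=ks, omega=omega,
        s_sites=s_sites, n_sites=n_sites,
        s_subs=s_subs, n_subs=n_subs,
        n_codons=used,
    )


def selection_test(result: KaKsResult, alpha: float = 0.05) -> KaKsResult:
    """Classify selection on a Ka/Ks estimate at significance ``alpha``.

    Under neutrality the observed substitutions split between synonymous
    and nonsynonymous sites in proportion to the site counts; the test is
    a one-degree-of-freedom chi-square of the observed (s_subs, n_subs)
    against that expectation.  Returns a copy of ``result`` with
    ``p_value``, ``selection`` (purifying / positive / ns) and, when the
    expected count in either class falls below one, a ``low_power`` flag
    forcing ``ns``.
    """
    if math.isnan(result.omega):
        return replace(result, selection="undefined", p_value=math.nan)
    total = result.s_subs + result.n_subs
    sites = result.s_sites + result.n_sites
    e_s = total * result.s_sites / sites
    e_n = total * result.n_sites / sites
    if min(e_s, e_n) < 1.0:
        return replace(result, selection="ns", p_value=math.nan,
                       low_power=True)
    stat = (result.s_subs - e_s) ** 2 / e_s + (result.n_subs - e_n) ** 2 / e_n
    p = float(chi2.sf(stat, df=1))
    if result.omega == 1.0:
        cls = "ns"
    elif p < alpha:
        cls = "purifying" if result.omega < 1.0 else "positive"
    else:
        cls = "ns"
    return replace(result, p_value=p, selection=cls)
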