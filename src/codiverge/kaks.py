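"""Nei–Gojobori (1986) synonymous/nonsynonymous analysis for in-frame pairs.

Site counting: at each codon position, the synonymous fraction is the
fraction of the non-stop single-nucleotide changes that preserve the amino
acid, so fractions at one position sum to 1 and a codon contributes exactly
3 sites.  Differences between two codons are averaged over all minimal
mutational pathways with equal weights, excluding pathways that pass
through a stop codon; if every pathway is blocked the codon pair is skipped
and recorded.  k_s = Sd/S and k_a = Nd/N with the Jukes–Cantor multiple-hit
correction applied when the proportion is below 3/4 (at the divergences
this package targets the correction is numerically negligible).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from Bio.Data import CodonTable

from .ortholog_io import CodonAlignment

__all__ = [
    "KaKsEstimate",
    "SENSE_CODONS",
    "count_syn_nonsyn_sites",
    "pathway_differences",
    "ka_ks_pair",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]  # standard genetic code
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))
AA = dict(_TABLE.forward_table)
_BASES = "ACGT"


def _check_sense(codon: str) -> str:
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} not allowed")
    if codon not in AA:
        raise ValueError(f"{codon!r} is not an unambiguous codon")
    return codon


def count_syn_nonsyn_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site fractions of one sense codon.

    Per position, s = fraction of the non-stop single-nucleotide neighbors
    that are synonymous and n = 1 - s; the totals sum to 3.
    """
    codon = _check_sense(codon)
    s_total = 0.0
    for pos in range(3):
        syn = 0
        considered = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            neighbor = codon[:pos] + base + codon[pos + 1 :]
            if neighbor in STOP_CODONS:
                continue
            considered += 1
            if AA[neighbor] == AA[codon]:
                syn += 1
        s_total += syn / considered if considered else 0.0
    return s_total, 3.0 - s_total


def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) change counts between two codons.

    Enumerates every ordering of the differing positions, drops orderings
    that pass through a stop codon, and averages with equal weights; the two
    counts sum to the Hamming distance.  Raises ValueError if all pathways
    are blocked by stops.
    """
    codon_a = _check_sense(codon_a)
    codon_b = _check_sense(codon_b)
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_counts, nonsyn_counts = [], []
    for order in permutations(diff_pos):
        current = codon_a
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if AA[nxt] == AA[current]:
                sd += 1
            else:
                nd += 1
            current = nxt
        if not blocked:
            syn_counts.append(sd)
            nonsyn_counts.append(nd)
    if not syn_counts:
        raise ValueError(
            f"all mutational pathways between {codon_a} and {codon_b} pass through stops"
        )
    return float(np.mean(syn_counts)), float(np.mean(nonsyn_counts))


def _jc_correct(p: float) -> tuple[float, bool]:
    """Jukes–Cantor distance; falls back to the raw proportion at p >= 3/4."""
    if p < 0.75:
        return -0.75 * np.log1p(-4.0 * p / 3.0), True
    return p, False


@dataclass
class KaKsEstimate:
    """NG86 site counts, pathway-averaged differences and rate estimates."""

    taxon_pair: tuple[str, str]
    S: float
    N: float
    Sd: float
    Nd: float
    ks: float
    ka: float
    n_codons_used: int
    n_codons_skipped: int = 0
    skipped_pairs: list[tuple[str, str]] = field(default_factory=list)
    corrected: bool = True

    @property
    def ratio(self) -> float:
        """k_s / k_a (inf when k_a is 0 and k_s positive; nan when both 0)."""
        if self.ka == 0:
            return np.inf if self.ks > 0 else np.nan
        return self.ks / self.ka


def ka_ks_pair(aln: CodonAlignment, a: str, b: str) -> KaKsEstimate:
    """NG86 k_s and k_a between two taxa of an in-frame alignment.

    Codons containing gaps, N or stop codons in either taxon are skipped.
    Site totals are the mean of the two sequences' counts; codon pairs whose
    pathways all traverse stops are skipped and listed.
    """
    seq_a, seq_b = aln.matrix[a].upper(), aln.matrix[b].upper()
    S = N = Sd = Nd = 0.0
    used = skipped = 0
    skipped_pairs: list[tuple[str, str]] = []
    site_cache: dict[str, tuple[float, float]] = {}
    path_cache: dict[tuple[str, str], tuple[float, float]] = {}
    for _, start, end in aln.gene_spans:
        for i in range(start, end, 3):
            ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
            if ca not in AA or cb not in AA:  # gap/N/stop in either
                skipped += 1
                continue
            key = (ca, cb) if ca <= cb else (cb, ca)
            if key not in path_cache:
                try:
                    path_cache[key] = pathway_differences(*key)
                except ValueError:
                    path_cache[key] = None  # type: ignore[assignment]
            pd = path_cache[key]
            if pd is None:
                skipped += 1
                skipped_pairs.append(key)
                continue
            for c in (ca, cb):
                if c not in site_cache:
                    site_cache[c] = count_syn_nonsyn_sites(c)
            sa, na = site_cache[ca]
            sb, nb = site_cache[cb]
            S += 0.5 * (sa + sb)
            N += 0.5 * (na + nb)
            Sd += pd[0]
            Nd += pd[1]
            used += 1
    if used == 0:
        raise ValueError("no usable codons in either sequence")
    ps = Sd / S if S > 0 else 0.0
    pa = Nd / N if N > 0 else 0.0
    ks, ok_s = _jc_correct(ps)
    ka, ok_a = _jc_correct(pa)
    return KaKsEstimate(
        taxon_pair=(a, b),
        S=S,
        N=N,
        Sd=Sd,
        Nd=Nd,
        ks=float(ks),
        ka=float(ka),
        n_codons_used=used,
        n_codons_skipped=skipped,
        skipped_pairs=skipped_pairs,
        corrected=ok_s and ok_a,
    )
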