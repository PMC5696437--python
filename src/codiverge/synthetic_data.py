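"""Synthetic inputs for every pipeline stage, with truth tables.

Coding alignments evolve on a rooted clock tree: per codon position p, the
expected number of substitutions per site on a branch is r_p times the
branch duration.  Selection on amino-acid changes is emulated by rejection:
a proposed nonsynonymous change is accepted with probability omega
(= target k_a/k_s), changes creating stop codons are always rejected, and
the proposal intensity is scaled by the expected acceptance fraction of the
ancestral codon composition so that the *realized* per-position rates match
the requested r_p in expectation.  With no transition bias in the proposal
kernel (the default) the realized k_a/k_s converges to omega, matching the
equal-weighting assumptions of the NG86 estimator.

Three acquisition scenarios drive multi-track (host nuclear /
mitochondrial / symbiont) datasets: cladogenic (symbiont and host diverge
together, symbiont/host synonymous rate fixed to a supplied calibration
ratio), introgression (mitochondrion and symbiont co-transferred, both
younger than the nuclear divergence), horizontal (symbiont younger than
both).  Depth profiles with planted copy-number variants emulate the
structure of real symbiont resequencing data, including regions the
reference genome carries in duplicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .kaks import AA, SENSE_CODONS, STOP_CODONS
from .ortholog_io import GeneAlignment
from .trees import Clade, ClockTree

__all__ = [
    "ScenarioConfig",
    "TruthTable",
    "ClockFixture",
    "DepthSim",
    "simulate_codon_alignment",
    "simulate_scenario",
    "ScenarioResult",
    "simulate_depth",
    "preset_wri_like",
    "preset_host_like",
    "table4_cnv_spec",
    "reference_duplicated_regions",
]

_BASES = "ACGT"
_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}


def _codon_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Neighbor class/id tables over the 61 sense codons.

    Returns (codon_bases[61,3], neighbor_class[61,3,3], neighbor_id[61,3,3])
    where class is 0=synonymous, 1=nonsynonymous, 2=stop and the third axis
    enumerates the three alternative bases in ACGT order.
    """
    codon_bases = np.empty((61, 3), dtype=np.uint8)
    neighbor_class = np.empty((61, 3, 3), dtype=np.uint8)
    neighbor_id = np.full((61, 3, 3), -1, dtype=np.int16)
    for ci, codon in enumerate(SENSE_CODONS):
        for pos in range(3):
            codon_bases[ci, pos] = _BASES.index(codon[pos])
            alts = [b for b in _BASES if b != codon[pos]]
            for ai, base in enumerate(alts):
                neighbor = codon[:pos] + base + codon[pos + 1 :]
                if neighbor in STOP_CODONS:
                    neighbor_class[ci, pos, ai] = 2
                else:
                    neighbor_class[ci, pos, ai] = (
                        0 if AA[neighbor] == AA[codon] else 1
                    )
                    neighbor_id[ci, pos, ai] = _CODON_INDEX[neighbor]
    return codon_bases, neighbor_class, neighbor_id


_CODON_BASES, _NEIGHBOR_CLASS, _NEIGHBOR_ID = _codon_tables()


def _alt_weights(kappa: float) -> np.ndarray:
    """Proposal weights over the three alternative bases, (61, 3, 3)."""
    w = np.ones((61, 3, 3))
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    for ci, codon in enumerate(SENSE_CODONS):
        for pos in range(3):
            alts = [b for b in _BASES if b != codon[pos]]
            for ai, base in enumerate(alts):
                if (codon[pos], base) in transitions:
                    w[ci, pos, ai] = kappa
    return w / w.sum(axis=2, keepdims=True)


def _accept_probs(ratio: float) -> tuple[float, float]:
    """(synonymous, nonsynonymous) acceptance probabilities realizing a
    nonsyn/syn acceptance ratio; ratios above 1 thin synonymous proposals."""
    if ratio <= 1.0:
        return 1.0, ratio
    return 1.0 / ratio, 1.0


def expected_acceptance(
    nonsyn_accept: float,
    kappa: float = 1.0,
    composition: np.ndarray | None = None,
    syn_accept: float = 1.0,
) -> np.ndarray:
    """Expected per-position proposal acceptance under the rejection rule.

    ``composition`` is a probability vector over the 61 sense codons
    (uniform by default).  Used to convert realized substitution-rate
    targets into proposal intensities.
    """
    w = _alt_weights(kappa)
    accept = np.where(
        _NEIGHBOR_CLASS == 0,
        syn_accept,
        np.where(_NEIGHBOR_CLASS == 1, nonsyn_accept, 0.0),
    )
    per_codon_pos = (w * accept).sum(axis=2)  # (61, 3)
    comp = (
        np.full(61, 1.0 / 61) if composition is None else np.asarray(composition)
    )
    return comp @ per_codon_pos  # (3,)


def _syn_nonsyn_proposal_fractions(
    kappa: float, composition: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position proposal weight landing on synonymous vs nonsynonymous
    changes, averaged over the codon composition."""
    w = _alt_weights(kappa)
    comp = np.full(61, 1.0 / 61) if composition is None else np.asarray(composition)
    syn = comp @ (w * (_NEIGHBOR_CLASS == 0)).sum(axis=2)
    nonsyn = comp @ (w * (_NEIGHBOR_CLASS == 1)).sum(axis=2)
    return syn, nonsyn


def _ng86_site_means(composition: np.ndarray | None = None) -> tuple[float, float]:
    """Mean NG86 synonymous/nonsynonymous sites per codon for a composition."""
    from .kaks import count_syn_nonsyn_sites

    counts = np.array([count_syn_nonsyn_sites(c) for c in SENSE_CODONS])
    comp = np.full(61, 1.0 / 61) if composition is None else np.asarray(composition)
    s_bar, n_bar = comp @ counts
    return float(s_bar), float(n_bar)


def predicted_ka_ks(
    accept_prob: float,
    rates: np.ndarray,
    kappa: float = 1.0,
    composition: np.ndarray | None = None,
) -> float:
    """Expected NG86 k_a/k_s of the generator at a given acceptance probability.

    Realized per-position totals are pinned to ``rates``; within position p
    the substitutions split syn:nonsyn as s_p : accept_prob * n_p, where
    s_p/n_p are the proposal-weight fractions.  Normalizing by the NG86 site
    means gives the ratio the estimator should recover.
    """
    sa, na = _accept_probs(accept_prob)
    syn_w, nonsyn_w = _syn_nonsyn_proposal_fractions(kappa, composition)
    share = sa * syn_w + na * nonsyn_w
    d = np.asarray(rates, dtype=float)
    if not d.any():
        return np.nan
    syn_subs = float((d * sa * syn_w / share).sum())
    nonsyn_subs = float((d * na * nonsyn_w / share).sum())
    s_bar, n_bar = _ng86_site_means(composition)
    if syn_subs == 0:
        return np.inf
    return (nonsyn_subs / n_bar) / (syn_subs / s_bar)


def _solve_acceptance(
    omega: float,
    rates: np.ndarray,
    kappa: float = 1.0,
    composition: np.ndarray | None = None,
) -> float:
    """Acceptance probability whose predicted NG86 k_a/k_s equals ``omega``."""
    from scipy.optimize import brentq

    def f(a: float) -> float:
        return predicted_ka_ks(a, rates, kappa, composition) - omega

    lo, hi = 1e-9, 50.0
    if not np.asarray(rates).any():
        return min(omega, 1.0)
    try:
        return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-10))
    except ValueError:
        return min(omega, 1.0)


def _weighted_syn_share(
    rates: np.ndarray, omega: float, kappa: float = 1.0
) -> float:
    """Realized synonymous substitutions per site per unit age, up to the
    common NG86 site normalization; used to match k_s ratios across tracks."""
    a = _solve_acceptance(omega, rates, kappa)
    sa, na = _accept_probs(a)
    syn_w, nonsyn_w = _syn_nonsyn_proposal_fractions(kappa)
    share = sa * syn_w + na * nonsyn_w
    return float((np.asarray(rates) * sa * syn_w / share).sum())


@dataclass
class TruthTable:
    """What the generator actually did, for independent validation."""

    ages: dict[tuple[str, ...], float]
    rates: tuple[float, float, float]
    omega: float
    kappa: float
    n_codons: int
    pair_differences: dict[tuple[str, str], dict[int, int]]
    n_proposed: int = 0
    n_accepted: int = 0
    meta: dict = field(default_factory=dict)


def simulate_codon_alignment(
    topology: str | ClockTree,
    ages: Mapping[Clade, float],
    rates: Sequence[float],
    omega: float = 1.0,
    n_codons: int | None = None,
    gene_lengths: Sequence[int] | None = None,
    kappa: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[GeneAlignment], TruthTable]:
    """Evolve in-frame coding sequence on a clock tree.

    ``rates`` are realized substitutions/site per unit age per codon
    position.  Provide either ``n_codons`` or per-gene ``gene_lengths``
    (base pairs, each divisible by 3).  Returns the per-gene alignments and
    a truth table with the realized pairwise difference counts.
    """
    tree = (
        topology
        if isinstance(topology, ClockTree)
        else ClockTree.from_newick(topology)
    )
    age_vec = tree.ages_vector(ages)
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (3,) or (rates < 0).any():
        raise ValueError("rates must be three non-negative values")
    if not 0 < omega <= 10:
        raise ValueError("omega must be in (0, 10]")
    if gene_lengths is not None:
        if any(l % 3 for l in gene_lengths):
            raise ValueError("gene lengths must be divisible by 3")
        n_codons = sum(gene_lengths) // 3
    if not n_codons:
        raise ValueError("provide n_codons or gene_lengths")
    if rng is None:
        rng = np.random.default_rng(seed)

    ancestral = rng.integers(0, 61, n_codons, dtype=np.int16)
    composition = np.bincount(ancestral, minlength=61) / n_codons
    ratio = _solve_acceptance(omega, rates, kappa, composition)
    sa, na = _accept_probs(ratio)
    alpha = expected_acceptance(na, kappa, composition, syn_accept=sa)
    lambdas = np.where(rates > 0, rates / np.maximum(alpha, 1e-12), 0.0)
    cum_w = _alt_weights(kappa).cumsum(axis=2)

    parent = [-1] * tree.n_nodes
    for i in tree.internal_nodes:
        for c in tree.children[i]:
            parent[c] = i
    states: list[np.ndarray | None] = [None] * tree.n_nodes
    states[tree.root] = ancestral
    n_proposed = n_accepted = 0
    order = [tree.root] + [n for n in reversed(range(tree.n_nodes)) if n != tree.root]
    for node in order:
        if node == tree.root:
            continue
        seq = states[parent[node]].copy()
        duration = age_vec[parent[node]] - age_vec[node]
        ev_codons, ev_pos = [], []
        for p in range(3):
            n_ev = rng.poisson(lambdas[p] * duration * n_codons)
            if n_ev:
                ev_codons.append(rng.integers(0, n_codons, n_ev))
                ev_pos.append(np.full(n_ev, p, dtype=np.int8))
        if ev_codons:
            codons = np.concatenate(ev_codons)
            positions = np.concatenate(ev_pos)
            perm = rng.permutation(codons.size)
            codons, positions = codons[perm], positions[perm]
            u_alt = rng.random(codons.size)
            u_acc = rng.random(codons.size)
            for k in range(codons.size):
                ci, p = int(codons[k]), int(positions[k])
                cid = seq[ci]
                alt = int((u_alt[k] > cum_w[cid, p]).sum())
                klass = _NEIGHBOR_CLASS[cid, p, alt]
                n_proposed += 1
                if klass == 2:
                    continue
                accept_p = sa if klass == 0 else na
                if accept_p < 1.0 and u_acc[k] >= accept_p:
                    continue
                seq[ci] = _NEIGHBOR_ID[cid, p, alt]
                n_accepted += 1
        states[node] = seq

    # realized pairwise differences per codon position
    tip_bases = {
        tree.taxa[t]: _CODON_BASES[states[t]] for t in range(tree.n_tips)
    }
    pair_diffs: dict[tuple[str, str], dict[int, int]] = {}
    for i, a in enumerate(tree.taxa):
        for b in tree.taxa[i + 1 :]:
            diff = tip_bases[a] != tip_bases[b]  # (n_codons, 3)
            pair_diffs[(a, b)] = {
                p + 1: int(diff[:, p].sum()) for p in range(3)
            }

    codon_strings = np.array(SENSE_CODONS)
    sequences = {
        tree.taxa[t]: "".join(codon_strings[states[t]]) for t in range(tree.n_tips)
    }
    if gene_lengths is None:
        gene_lengths = [3 * n_codons]
    genes: list[GeneAlignment] = []
    offset = 0
    width = len(str(len(gene_lengths)))
    for gi, glen in enumerate(gene_lengths):
        genes.append(
            GeneAlignment(
                gene_id=f"gene{gi + 1:0{width}d}",
                sequences={
                    t: s[offset : offset + glen] for t, s in sequences.items()
                },
            )
        )
        offset += glen
    truth = TruthTable(
        ages={tuple(sorted(k)): v for k, v in ages.items()},
        rates=tuple(float(r) for r in rates),
        omega=omega,
        kappa=kappa,
        n_codons=n_codons,
        pair_differences=pair_diffs,
        n_proposed=n_proposed,
        n_accepted=n_accepted,
    )
    return genes, truth


def _gene_lengths(total_bp: int, n_genes: int) -> list[int]:
    """Split a total length into ``n_genes`` in-frame genes summing exactly."""
    total_codons = total_bp // 3
    if total_codons < n_genes:
        raise ValueError("fewer codons than genes")
    base = total_codons // n_genes
    extra = total_codons - base * n_genes
    return [(base + (1 if i < extra else 0)) * 3 for i in range(n_genes)]


@dataclass
class ClockFixture:
    """A ready-to-simulate clock setup (tree, ages, rates, genes)."""

    tree: ClockTree
    ages: dict[Clade, float]
    rates: tuple[float, float, float]
    omega: float
    gene_lengths: list[int]
    reference: Clade

    def simulate(
        self, seed: int | None = None, rng: np.random.Generator | None = None
    ) -> tuple[list[GeneAlignment], TruthTable]:
        return simulate_codon_alignment(
            self.tree,
            self.ages,
            self.rates,
            omega=self.omega,
            gene_lengths=self.gene_lengths,
            seed=seed,
            rng=rng,
        )


def preset_wri_like(
    total_bp: int = 704_883,
    n_genes: int = 703,
    outgroup_ratio: float = 3.51,
    divergences: tuple[float, float, float] = (5.0e-5, 3.2e-5, 4.0e-5),
) -> ClockFixture:
    """Three closely related symbiont genomes: a sister pair at per-position
    divergences of a few 1e-5 and an outgroup 3.51 times older, over 703
    single-copy genes totalling 704,883 bp by default.  ``total_bp`` may be
    scaled down (gene count shrinks proportionally)."""
    if total_bp != 704_883:
        n_genes = max(1, round(703 * total_bp / 704_883))
        total_bp = (total_bp // 3) * 3
    tree = ClockTree.from_newick("((wSuz,wSpc),wRi);")
    ages = {
        frozenset({"wSuz", "wSpc"}): 1.0,
        frozenset({"wSuz", "wSpc", "wRi"}): outgroup_ratio,
    }
    rates = tuple(d / 2.0 for d in divergences)
    return ClockFixture(
        tree=tree,
        ages=ages,
        rates=rates,
        omega=1.0,
        gene_lengths=_gene_lengths(total_bp, n_genes),
        reference=frozenset({"wSuz", "wSpc"}),
    )


def preset_host_like(
    n_genes: int = 18,
    gene_bp: int = 1500,
    divergences: tuple[float, float, float] = (1.10e-2, 4.73e-3, 9.20e-2),
    outgroup_age: float = 1.96,
    second_clade_age: float = 0.72,
    root_age: float = 3.0,
    omega: float = 0.05,
) -> ClockFixture:
    """Five host nuclear genomes over 18 concatenated loci: focal sister
    pair at age 1, their outgroup at 1.96, and a second species pair whose
    divergence is 0.72 on the same scale."""
    tree = ClockTree.from_newick(
        "(((D_suzukii,D_subpulchrella),D_biarmipes),(D_melanogaster,D_simulans));"
    )
    pair = frozenset({"D_suzukii", "D_subpulchrella"})
    ages = {
        pair: 1.0,
        frozenset({"D_suzukii", "D_subpulchrella", "D_biarmipes"}): outgroup_age,
        frozenset({"D_melanogaster", "D_simulans"}): second_clade_age,
        frozenset(tree.taxa): root_age,
    }
    rates = tuple(d / 2.0 for d in divergences)
    return ClockFixture(
        tree=tree,
        ages=ages,
        rates=rates,
        omega=omega,
        gene_lengths=[gene_bp] * n_genes,
        reference=pair,
    )


@dataclass
class ScenarioConfig:
    """Study conditions for a three-track acquisition scenario."""

    mode: Literal["cladogenic", "introgression", "horizontal"]
    seed: int | None = None
    host_taxa: tuple[str, str, str] = (
        "D_suzukii",
        "D_subpulchrella",
        "D_biarmipes",
    )
    symbiont_taxa: tuple[str, str, str] = ("wSuz", "wSpc", "wOut")
    # per-position realized divergence of the focal host pair
    nuclear_divergences: tuple[float, float, float] = (1.10e-2, 4.73e-3, 9.20e-2)
    host_outgroup_age: float = 1.96
    symbiont_outgroup_ratio: float = 3.51
    calibration_ratio: float = 0.13  # symbiont/host synonymous-rate ratio
    transfer_age: float | None = None  # symbiont coalescence, host-pair age = 1
    mito_age: float | None = None
    omega_host: float = 0.05
    omega_mito: float = 0.05
    omega_symbiont: float = 1.0
    nuclear_genes: int = 18
    nuclear_gene_bp: int = 1500
    mito_bp: int = 12_000
    symbiont_bp: int = 704_883
    symbiont_genes: int = 703

    def __post_init__(self) -> None:
        defaults = {
            "cladogenic": (1.0, 1.0),
            "introgression": (0.1, 0.1),
            "horizontal": (0.01, 1.0),
        }
        if self.mode not in defaults:
            raise ValueError(f"unknown mode {self.mode!r}")
        d_transfer, d_mito = defaults[self.mode]
        if self.transfer_age is None:
            self.transfer_age = d_transfer
        if self.mito_age is None:
            self.mito_age = d_mito
        self.validate()

    def validate(self) -> None:
        t, m = self.transfer_age, self.mito_age
        if self.mode == "cladogenic" and not (t == m == 1.0):
            raise ValueError("cladogenic: symbiont and mito ages must equal 1")
        if self.mode == "introgression" and not (t == m < 1.0):
            raise ValueError("introgression: mito age must equal transfer age < 1")
        if self.mode == "horizontal" and not (t < m <= 1.0):
            raise ValueError("horizontal: transfer age < mito age <= 1")


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    nuclear: list[GeneAlignment]
    mito: list[GeneAlignment]
    symbiont: list[GeneAlignment]
    truth: dict[str, TruthTable]


def simulate_scenario(cfg: ScenarioConfig) -> ScenarioResult:
    """Generate nuclear, mitochondrial and symbiont alignments for a scenario.

    All tracks share the host topology.  Mitochondrial per-position rates
    equal the nuclear rates (so mito divergences are directly on the
    nuclear scale); symbiont *synonymous* rates are ``calibration_ratio``
    times the host's, implemented by rescaling the realized-rate targets by
    the tracks' expected proposal-acceptance fractions so that the
    synonymous-rate ratio, which is what k_s measures, hits the calibration
    ratio regardless of the differing omegas.
    """
    rng = np.random.default_rng(cfg.seed)
    host_rates = np.array(cfg.nuclear_divergences) / 2.0
    ha, hb, hout = cfg.host_taxa
    sa, sb, sout = cfg.symbiont_taxa

    host_tree = ClockTree.from_newick(f"(({ha},{hb}),{hout});")
    host_ages = {
        frozenset({ha, hb}): 1.0,
        frozenset({ha, hb, hout}): cfg.host_outgroup_age,
    }
    nuclear, truth_nuc = simulate_codon_alignment(
        host_tree,
        host_ages,
        host_rates,
        omega=cfg.omega_host,
        gene_lengths=[cfg.nuclear_gene_bp] * cfg.nuclear_genes,
        rng=rng,
    )

    mito_ages = {
        frozenset({ha, hb}): cfg.mito_age,
        frozenset({ha, hb, hout}): cfg.host_outgroup_age,
    }
    mito, truth_mito = simulate_codon_alignment(
        host_tree,
        mito_ages,
        host_rates,
        omega=cfg.omega_mito,
        gene_lengths=[cfg.mito_bp],
        rng=rng,
    )

    # match synonymous (not total) rates to the calibration ratio
    syn_host = _weighted_syn_share(host_rates, cfg.omega_host)
    syn_symb = _weighted_syn_share(host_rates, cfg.omega_symbiont)
    symb_rates = cfg.calibration_ratio * host_rates * syn_host / syn_symb
    symb_tree = ClockTree.from_newick(f"(({sa},{sb}),{sout});")
    symb_ages = {
        frozenset({sa, sb}): cfg.transfer_age,
        frozenset({sa, sb, sout}): cfg.symbiont_outgroup_ratio
        * max(cfg.transfer_age, 1.0),
    }
    symbiont, truth_symb = simulate_codon_alignment(
        symb_tree,
        symb_ages,
        symb_rates,
        omega=cfg.omega_symbiont,
        gene_lengths=_gene_lengths((cfg.symbiont_bp // 3) * 3, cfg.symbiont_genes),
        rng=rng,
    )
    for t, label in ((truth_nuc, "nuclear"), (truth_mito, "mito"), (truth_symb, "symbiont")):
        t.meta.update(mode=cfg.mode, track=label)
    return ScenarioResult(
        config=cfg,
        nuclear=nuclear,
        mito=mito,
        symbiont=symbiont,
        truth={"nuclear": truth_nuc, "mito": truth_mito, "symbiont": truth_symb},
    )


def table4_cnv_spec() -> list[tuple[int, int, int, int]]:
    """Planted variants shaped like real symbiont resequencing results:
    two 22.5-kb gains inside reference-duplicated prophage regions (2 -> 3),
    one 23-kb loss (1 -> 0) and one 2.5-kb gain (1 -> 2).
    Intervals are 0-based half-open (start, end, from_copy, to_copy)."""
    return [
        (570_000, 592_500, 2, 3),
        (733_000, 756_000, 1, 0),
        (1_077_500, 1_100_000, 2, 3),
        (1_345_000, 1_347_500, 1, 2),
    ]


def reference_duplicated_regions() -> list[tuple[int, int]]:
    """The two near-identical prophage copies the reference genome carries,
    treated as ploidy 2 when calling copy number."""
    return [(565_000, 636_000), (1_071_000, 1_142_000)]


@dataclass
class DepthSim:
    contig: str
    genome_length: int
    mean_depth: float
    sample: np.ndarray   # per-base depth
    control: np.ndarray
    cnv_spec: list[tuple[int, int, int, int]]
    duplicated_regions: list[tuple[int, int]]


def simulate_depth(
    genome_length: int = 1_450_000,
    mean_depth: float = 30.0,
    cnv_spec: Sequence[tuple[int, int, int, int]] | None = None,
    duplicated_regions: Sequence[tuple[int, int]] | None = None,
    seed: int | None = None,
    contig: str = "wRef",
) -> DepthSim:
    """Per-base Poisson depth for a sample with planted CNVs and a clean control.

    The expected sample depth over a variant (start, end, from, to) is
    mean_depth * to/from -- reads from extra copies pile onto the reference
    copies -- and mean_depth elsewhere; the control is uniform.  Variant
    intervals must not overlap.
    """
    if cnv_spec is None:
        cnv_spec = table4_cnv_spec()
    if duplicated_regions is None:
        duplicated_regions = reference_duplicated_regions()
    spec = sorted(cnv_spec)
    for (s1, e1, *_), (s2, e2, *_) in zip(spec, spec[1:]):
        if s2 < e1:
            raise ValueError("cnv intervals overlap")
    for start, end, frm, to in spec:
        if not (0 <= start < end <= genome_length):
            raise ValueError(f"cnv interval ({start}, {end}) outside genome")
        if frm == to:
            raise ValueError("cnv must change copy number")
    rng = np.random.default_rng(seed)
    rate = np.full(genome_length, float(mean_depth))
    for start, end, frm, to in spec:
        if frm <= 0:
            raise ValueError("from_copy must be positive")
        rate[start:end] = mean_depth * to / frm
    sample = rng.poisson(rate).astype(float)
    control = rng.poisson(np.full(genome_length, float(mean_depth))).astype(float)
    return DepthSim(
        contig=contig,
        genome_length=genome_length,
        mean_depth=float(mean_depth),
        sample=sample,
        control=control,
        cnv_spec=list(spec),
        duplicated_regions=list(duplicated_regions),
    )
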