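"""Coalescent and 454-style synthetic data generation.

This module produces every input the downstream analyses need without any
external data: haplotype alignments from a standard neutral coalescent
(optionally with intra-locus recombination and exponential growth), a
two-population split model whose gene trees are recorded so the true
lineage-sorting state (polyphyly / paraphyly / reciprocal monophyly) is
known, and pyrosequencing-style read pileups with emulsion-PCR duplicates,
homopolymer undercalls, allelic imbalance and optional allelic dropout.

Time is measured in units of 4N generations (the convention of Hudson's
``ms``), so a locus-wide ``theta`` = 4Nµ·L and ``rho`` = 4Nr·L. Mutations
follow the infinite-sites model on a continuous unit interval and are mapped
to discrete base positions afterwards (collisions re-drawn).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoalescentParams:
    """Single-population neutral coalescent parameters for one locus.

    theta and rho are locus-wide (per-locus, not per-site) population-scaled
    rates; growth_rate is the exponential growth parameter in units of
    1/(4N) generations (0 = constant size, looking-backward decline).
    """

    n_samples: int
    locus_length: int
    theta: float
    rho: float = 0.0
    growth_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 chromosomes")
        if self.locus_length < 1:
            raise ValueError("locus_length must be >= 1")
        if self.theta < 0 or self.rho < 0:
            raise ValueError("theta and rho must be non-negative")
        if self.growth_rate < 0:
            raise ValueError("only non-negative growth is supported")


@dataclass(frozen=True)
class SplitModelParams:
    """Two-population clean-split (isolation) model.

    split_time is in coalescent units of 4N_ancestral generations;
    size_ratios are the two descendant effective sizes relative to the
    ancestral population (1.0, 1.0 keeps all sizes equal).
    """

    n_per_pop: tuple[int, int]
    split_time: float
    size_ratios: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if min(self.n_per_pop) < 1:
            raise ValueError("both populations must be non-empty")
        if self.split_time < 0:
            raise ValueError("split_time must be >= 0")
        if min(self.size_ratios) <= 0:
            raise ValueError("size ratios must be positive")


@dataclass
class HaplotypeAlignment:
    """Aligned haplotypes with population labels and an optional outgroup."""

    sequences: list[str]
    labels: list[str]
    pop_map: dict[str, str]
    outgroup_label: str | None
    locus_length: int
    gene_tree: str | None = None  # newick, recorded truth for split sims

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.labels):
            raise ValueError("one label per sequence required")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("sequences must be aligned to equal length")
        for lab in self.labels:
            if lab not in self.pop_map and lab != self.outgroup_label:
                raise ValueError(f"label {lab!r} missing from pop_map")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.labels:
            if lab in self.pop_map:
                seen.setdefault(self.pop_map[lab], None)
        return list(seen)

    def sequences_for(self, population: str) -> list[str]:
        return [s for s, lab in zip(self.sequences, self.labels)
                if self.pop_map.get(lab) == population]

    @property
    def outgroup_sequence(self) -> str | None:
        if self.outgroup_label is None:
            return None
        return self.sequences[self.labels.index(self.outgroup_label)]


@dataclass(frozen=True)
class ReadSimConfig:
    """Error model for synthetic pyrosequencing reads.

    allele_balance is the expected minor-allele read fraction at truly
    heterozygous sites (0.5 = unbiased amplification); dropout silences the
    second haplotype entirely.  homopolymer_error_rate scales the per-run
    undercall probability as rate x (run length - 1), capped at 0.5.
    base_quality_profile is (values, probabilities) for per-base phred
    scores.  Pyrosequencing quality values predominantly reflect
    homopolymer/indel uncertainty, which this model simulates as its own
    channel, so only substitution_fraction of the phred-implied error
    probability is realized as base substitutions (the published error
    decompositions for this platform put substitutions at roughly 5-10%
    of the total error budget).
    """

    mean_coverage: float = 20.0
    duplicate_rate: float = 0.1
    allele_balance: float = 0.5
    dropout: bool = False
    homopolymer_error_rate: float = 0.02
    substitution_fraction: float = 0.1
    base_quality_profile: tuple[tuple[int, ...], tuple[float, ...]] = (
        (20, 25, 30, 35, 40), (0.05, 0.15, 0.40, 0.30, 0.10))
    read_length_mean: float = 250.0
    read_length_sd: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.duplicate_rate < 1):
            raise ValueError("duplicate_rate must be in [0, 1)")
        if not (0 < self.allele_balance <= 0.5):
            raise ValueError("allele_balance must be in (0, 0.5]")
        if self.mean_coverage <= 0:
            raise ValueError("coverage must be positive")


# ---------------------------------------------------------------------------
# genealogy machinery
# ---------------------------------------------------------------------------

class _Node:
    """Genealogy node; leaves carries the sample indices below it."""

    __slots__ = ("time", "children", "leaves")

    def __init__(self, time: float, children: tuple, leaves: frozenset):
        self.time = time
        self.children = children
        self.leaves = leaves


class _Segment:
    """Half-open interval of ancestral material pointing at a tree node."""

    __slots__ = ("left", "right", "node")

    def __init__(self, left: float, right: float, node: _Node):
        self.left = left
        self.right = right
        self.node = node


def _coal_wait(rate: float, growth: float, t: float, rng) -> float:
    """Waiting time to the next coalescence under exponential growth.

    Backwards in time the coalescence intensity is rate * exp(growth * t);
    inversion of the cumulative hazard gives the draw in closed form.
    """
    e = rng.exponential()
    if growth == 0.0:
        return e / rate
    return math.log1p(growth * e * math.exp(-growth * t) / rate) / growth


def _merge_lineages(a: list[_Segment], b: list[_Segment], t: float,
                    n: int, done: list) -> list[_Segment]:
    """Coalesce two lineages; completed (sample-wide MRCA) intervals go to done."""
    out: list[_Segment] = []
    i = j = 0
    while i < len(a) and j < len(b):
        sa, sb = a[i], b[j]
        if sa.right <= sb.left:
            out.append(sa)
            i += 1
            continue
        if sb.right <= sa.left:
            out.append(sb)
            j += 1
            continue
        if sa.left < sb.left:
            out.append(_Segment(sa.left, sb.left, sa.node))
            a[i] = sa = _Segment(sb.left, sa.right, sa.node)
        elif sb.left < sa.left:
            out.append(_Segment(sb.left, sa.left, sb.node))
            b[j] = sb = _Segment(sa.left, sb.right, sb.node)
        r = min(sa.right, sb.right)
        node = _Node(t, (sa.node, sb.node), sa.node.leaves | sb.node.leaves)
        if len(node.leaves) == n:
            done.append((sa.left, r, node))
        else:
            out.append(_Segment(sa.left, r, node))
        if sa.right > r:
            a[i] = _Segment(r, sa.right, sa.node)
        else:
            i += 1
        if sb.right > r:
            b[j] = _Segment(r, sb.right, sb.node)
        else:
            j += 1
    out.extend(a[i:])
    out.extend(b[j:])
    out.sort(key=lambda s: s.left)
    return out


def _sim_marginal_trees(n: int, rho: float, growth: float,
                        rng) -> list[tuple[float, float, _Node]]:
    """Hudson coalescent with recombination over the unit interval.

    Returns (left, right, root) marginal genealogies covering [0, 1).
    With rho == 0 a single Kingman tree is returned.
    """
    if rho == 0.0:
        active_nodes = [_Node(0.0, (), frozenset([i])) for i in range(n)]
        t = 0.0
        while len(active_nodes) > 1:
            k = len(active_nodes)
            t += _coal_wait(k * (k - 1), growth, t, rng)
            i, j = rng.choice(k, size=2, replace=False)
            i, j = (int(i), int(j)) if i < j else (int(j), int(i))
            b = active_nodes.pop(j)
            a = active_nodes.pop(i)
            active_nodes.append(_Node(t, (a, b), a.leaves | b.leaves))
        return [(0.0, 1.0, active_nodes[0])]

    active: list[list[_Segment]] = [
        [_Segment(0.0, 1.0, _Node(0.0, (), frozenset([i])))] for i in range(n)]
    done: list[tuple[float, float, _Node]] = []
    t = 0.0
    while len(active) > 1:
        k = len(active)
        spans = [segs[-1].right - segs[0].left for segs in active]
        rec_rate = rho * sum(spans)
        w_coal = _coal_wait(k * (k - 1), growth, t, rng)
        w_rec = rng.exponential() / rec_rate if rec_rate > 0 else math.inf
        if w_coal <= w_rec:
            t += w_coal
            i, j = rng.choice(k, size=2, replace=False)
            i, j = (int(i), int(j)) if i < j else (int(j), int(i))
            b = active.pop(j)
            a = active.pop(i)
            merged = _merge_lineages(a, b, t, n, done)
            if merged:
                active.append(merged)
        else:
            t += w_rec
            total = sum(spans)
            u = rng.uniform(0, total)
            idx = 0
            acc = 0.0
            for idx, sp in enumerate(spans):
                acc += sp
                if u < acc:
                    break
            segs = active[idx]
            x = rng.uniform(segs[0].left, segs[-1].right)
            left: list[_Segment] = []
            right: list[_Segment] = []
            for s in segs:
                if s.right <= x:
                    left.append(s)
                elif s.left >= x:
                    right.append(s)
                else:
                    left.append(_Segment(s.left, x, s.node))
                    right.append(_Segment(x, s.right, s.node))
            if left and right:
                active[idx] = left
                active.append(right)
    return sorted(done, key=lambda d: d[0])


def _drop_mutations(trees, theta: float, rng) -> list[tuple[float, frozenset]]:
    """Poisson mutations on branches; returns (position in [0,1), carrier set)."""
    muts: list[tuple[float, frozenset]] = []
    for left, right, root in trees:
        branches: list[_Node] = []
        lens: list[float] = []
        stack = [root]
        while stack:
            v = stack.pop()
            for c in v.children:
                branches.append(c)
                lens.append(v.time - c.time)
                stack.append(c)
        total = sum(lens)
        if total <= 0:
            continue
        n_mut = rng.poisson(theta * (right - left) * total)
        if n_mut == 0:
            continue
        probs = np.asarray(lens) / total
        chosen = rng.choice(len(branches), size=n_mut, p=probs)
        positions = rng.uniform(left, right, size=n_mut)
        for b, p in zip(chosen, positions):
            muts.append((float(p), branches[int(b)].leaves))
    muts.sort(key=lambda m: m[0])
    return muts


def _simulate_counts(params: CoalescentParams, rng) -> np.ndarray:
    """Derived-allele counts at segregating sites (positions discarded)."""
    trees = _sim_marginal_trees(params.n_samples, params.rho,
                                params.growth_rate, rng)
    muts = _drop_mutations(trees, params.theta, rng)
    return np.array([len(c) for _, c in muts], dtype=np.int64)


def _positions_to_sites(positions: list[float], length: int, rng) -> list[int]:
    """Map continuous positions to distinct integer sites, re-drawing collisions."""
    used: set[int] = set()
    sites: list[int] = []
    for p in positions:
        s = min(int(p * length), length - 1)
        while s in used:
            s = int(rng.integers(0, length))
        used.add(s)
        sites.append(s)
    return sites


def _realize_alignment(muts, n: int, length: int, pop_of, labels, rng,
                       outgroup_label: str = "outgroup",
                       gene_tree: str | None = None) -> HaplotypeAlignment:
    """Turn mutation carrier sets into concrete A/C/G/T haplotypes.

    The ancestral sequence doubles as the outgroup record: with ~1%
    outgroup divergence and infinite-sites data, the outgroup state is the
    ancestral state at every polymorphic site.
    """
    if len(muts) > length:
        raise ValueError("more segregating sites than bases; increase length")
    ref = rng.choice(list(_BASES), size=length)
    seqs = np.tile(ref, (n, 1))
    sites = _positions_to_sites([p for p, _ in muts], length, rng)
    for site, (_, carriers) in zip(sites, muts):
        anc = ref[site]
        derived = _BASES[(_BASES.index(anc) + int(rng.integers(1, 4))) % 4]
        for leaf in carriers:
            seqs[leaf, site] = derived
    sequences = ["".join(row) for row in seqs] + ["".join(ref)]
    all_labels = list(labels) + [outgroup_label]
    return HaplotypeAlignment(
        sequences=sequences, labels=all_labels, pop_map=dict(pop_of),
        outgroup_label=outgroup_label, locus_length=length,
        gene_tree=gene_tree)


# ---------------------------------------------------------------------------
# public simulation operations
# ---------------------------------------------------------------------------

def simulate_locus(params: CoalescentParams, seed: int,
                   population: str = "pop1") -> HaplotypeAlignment:
    """Simulate one locus under the single-population neutral model.

    Returns an alignment of n_samples haplotypes plus an all-ancestral
    outgroup surrogate; every segregating site is biallelic.
    """
    rng = np.random.default_rng(seed)
    trees = _sim_marginal_trees(params.n_samples, params.rho,
                                params.growth_rate, rng)
    muts = _drop_mutations(trees, params.theta, rng)
    labels = [f"{population}_{i}" for i in range(params.n_samples)]
    pop_of = {lab: population for lab in labels}
    return _realize_alignment(muts, params.n_samples, params.locus_length,
                              pop_of, labels, rng)


def _newick(node: _Node, names: list[str]) -> str:
    if not node.children:
        (leaf,) = node.leaves
        return names[leaf]
    parts = []
    for c in node.children:
        parts.append(f"{_newick(c, names)}:{node.time - c.time:.6g}")
    return "(" + ",".join(parts) + ")"


def _sim_split_tree(params: SplitModelParams, rng) -> _Node:
    n1, n2 = params.n_per_pop
    r1, r2 = params.size_ratios
    demes: list[list[_Node]] = [
        [_Node(0.0, (), frozenset([i])) for i in range(n1)],
        [_Node(0.0, (), frozenset([n1 + i])) for i in range(n2)]]
    t = 0.0

    def coalesce(pool: list[_Node], t: float) -> None:
        k = len(pool)
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        b = pool.pop(j)
        a = pool.pop(i)
        pool.append(_Node(t, (a, b), a.leaves | b.leaves))

    while True:
        rates = [len(demes[0]) * (len(demes[0]) - 1) / r1,
                 len(demes[1]) * (len(demes[1]) - 1) / r2]
        total = rates[0] + rates[1]
        if total == 0:
            break
        w = rng.exponential() / total
        if t + w >= params.split_time:
            break
        t += w
        which = 0 if rng.uniform(0, total) < rates[0] else 1
        coalesce(demes[which], t)
    t = max(t, params.split_time)
    pool = demes[0] + demes[1]
    while len(pool) > 1:
        k = len(pool)
        t += rng.exponential() / (k * (k - 1))
        coalesce(pool, t)
    return pool[0]


def simulate_split(params: SplitModelParams, theta: float, seed: int,
                   locus_length: int = 10_000,
                   pop_names: tuple[str, str] = ("pop1", "pop2"),
                   ) -> HaplotypeAlignment:
    """Simulate one locus under a two-population clean split.

    The realized gene tree is stored (newick, branch lengths in 4N units)
    so the lineage-sorting state of each replicate is known truth.
    """
    rng = np.random.default_rng(seed)
    n1, n2 = params.n_per_pop
    root = _sim_split_tree(params, rng)
    labels = ([f"{pop_names[0]}_{i}" for i in range(n1)]
              + [f"{pop_names[1]}_{i}" for i in range(n2)])
    pop_of = {lab: (pop_names[0] if i < n1 else pop_names[1])
              for i, lab in enumerate(labels)}
    newick = _newick(root, labels) + ";"
    muts = _drop_mutations([(0.0, 1.0, root)], theta, rng)
    return _realize_alignment(muts, n1 + n2, locus_length, pop_of, labels,
                              rng, gene_tree=newick)


def simulate_reads(haplotypes: tuple[str, str], config: ReadSimConfig):
    """Simulate a pyrosequencing-style pileup from a diploid pair of haplotypes.

    Returns a :class:`pansort.snp_calling.ReadPileup` whose consensus is the
    first haplotype (standing in for the assembly consensus) and whose
    truth_hets records the planted heterozygous positions.
    """
    from .snp_calling import Read, ReadPileup

    hap1, hap2 = haplotypes
    if len(hap1) == 0 or len(hap2) == 0:
        raise ValueError("haplotypes must be non-empty")
    if len(hap1) != len(hap2):
        raise ValueError("haplotypes must have equal length")
    length = len(hap1)
    rng = np.random.default_rng(config.seed)
    qvals, qprobs = config.base_quality_profile
    qvals_arr = np.asarray(qvals)
    qprobs_arr = np.asarray(qprobs, dtype=float)
    qprobs_arr = qprobs_arr / qprobs_arr.sum()

    n_templates = max(1, int(round(
        config.mean_coverage * length / config.read_length_mean)))
    templates = []
    for _ in range(n_templates):
        rlen = int(np.clip(rng.normal(config.read_length_mean,
                                      config.read_length_sd), 50, length))
        start = int(rng.integers(0, max(1, length - rlen + 1)))
        strand = "+" if rng.random() < 0.5 else "-"
        if config.dropout:
            hap = 0
        else:
            hap = 1 if rng.random() < config.allele_balance else 0
        templates.append((start, rlen, strand, hap))
    # emulsion-PCR duplicates: same template molecule, independent base calls
    for tpl in list(templates):
        if rng.random() < config.duplicate_rate:
            templates.append(tpl)

    reads = []
    for start, rlen, strand, hap in templates:
        source = hap2 if hap else hap1
        bases = list(source[start:start + rlen])
        # homopolymer undercalls, shown as alignment gaps at the run's end
        i = 0
        while i < rlen:
            j = i
            while j + 1 < rlen and bases[j + 1] == bases[i] and bases[j] != "-":
                j += 1
            run = j - i + 1
            if run >= 2 and bases[i] != "-":
                p_err = min(0.5, config.homopolymer_error_rate * (run - 1))
                if rng.random() < p_err:
                    bases[j] = "-"
            i = j + 1
        quals = rng.choice(qvals_arr, size=rlen, p=qprobs_arr)
        for k in range(rlen):
            if bases[k] == "-":
                continue
            p_sub = config.substitution_fraction * 10.0 ** (-quals[k] / 10.0)
            if rng.random() < p_sub:
                alt = _BASES[(_BASES.index(bases[k]) + int(rng.integers(1, 4))) % 4] \
                    if bases[k] in _BASES else bases[k]
                bases[k] = alt
        kept_quals = tuple(int(q) for q, b in zip(quals, bases) if b != "-")
        reads.append(Read(start=start, strand=strand, bases="".join(bases),
                          qualities=kept_quals,
                          read_quality=float(np.mean(kept_quals))
                          if kept_quals else 0.0))
    truth = tuple(i for i in range(length) if hap1[i] != hap2[i])
    return ReadPileup(consensus=hap1, reads=reads, truth_hets=truth)


def sample_null_hyperparams(locus_rate_estimates, locus_recomb_estimates,
                            loci=None, reps: int = 1000, seed: int = 0):
    """Moment-match per-locus rate estimates to the null model's hyperpriors.

    theta estimates are matched to a Gamma(shape, scale) by
    shape = m^2/v, scale = v/m; recombination estimates to a log-normal
    matched on the natural scale.  Zero-variance inputs degenerate to point
    masses (Gamma encoded as (inf, m); log-normal as sdlog = 0) with a
    warning.  Returns a :class:`pansort.neutrality.NullModelConfig`.
    """
    from .neutrality import NullModelConfig

    th = np.asarray(locus_rate_estimates, dtype=float)
    rh = np.asarray(locus_recomb_estimates, dtype=float)
    if th.size < 2 or rh.size < 2:
        raise ValueError("need at least 2 loci to fit hyperparameters")
    if (th <= 0).any() or (rh <= 0).any():
        raise ValueError("rate estimates must be positive")

    m, v = float(th.mean()), float(th.var(ddof=1))
    if v == 0.0:
        warnings.warn("zero variance in theta estimates; using a point mass")
        theta_gamma = (math.inf, m)
    else:
        theta_gamma = (m * m / v, v / m)

    mr, vr = float(rh.mean()), float(rh.var(ddof=1))
    if vr == 0.0:
        warnings.warn("zero variance in rho estimates; using a point mass")
        rho_lognormal = (math.log(mr), 0.0)
    else:
        s2 = math.log1p(vr / (mr * mr))
        rho_lognormal = (math.log(mr) - s2 / 2.0, math.sqrt(s2))

    return NullModelConfig(reps=reps, loci=list(loci or []),
                           theta_gamma=theta_gamma,
                           rho_lognormal=rho_lognormal, seed=seed)


# ---------------------------------------------------------------------------
# interchange formats
# ---------------------------------------------------------------------------

def write_fasta(aln: HaplotypeAlignment, path) -> None:
    """Write one record per chromosome; population carried in the description."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = []
    for lab, seq in zip(aln.labels, aln.sequences):
        pop = ("outgroup" if lab == aln.outgroup_label
               else aln.pop_map.get(lab, ""))
        records.append(SeqRecord(Seq(seq), id=lab, description=f"pop={pop}"))
    seqio_write(records, str(path), "fasta")


def to_ms_text(aln: HaplotypeAlignment) -> str:
    """Render an alignment in ms-style text (0 = outgroup/ancestral state)."""
    if aln.outgroup_label is None:
        raise ValueError("ms rendering needs the outgroup to polarize states")
    out = aln.outgroup_sequence
    ingroup = [(lab, seq) for lab, seq in zip(aln.labels, aln.sequences)
               if lab != aln.outgroup_label]
    seg_sites = [i for i in range(aln.locus_length)
                 if len({s[i] for _, s in ingroup} | {out[i]}) > 1]
    lines = ["//", f"segsites: {len(seg_sites)}"]
    if seg_sites:
        pos = " ".join(f"{(i + 0.5) / aln.locus_length:.6f}" for i in seg_sites)
        lines.append(f"positions: {pos}")
        for _, seq in ingroup:
            lines.append("".join("0" if seq[i] == out[i] else "1"
                                 for i in seg_sites))
    return "\n".join(lines) + "\n"
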