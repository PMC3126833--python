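"""Population-genetic summary statistics, Ne estimation and differentiation.

Per-locus statistics follow the classical estimators: Watterson's
theta_w = S / (a_n L) from the segregating-site count, nucleotide
diversity pi as the mean pairwise difference per site, Tajima's D and
Fu & Li's D* (the no-outgroup singleton statistic, with the corrected
variance constants).  Effective population size comes from
Ne = theta_w / (4 mu) with the per-generation per-site mutation rate
mu = (d / 2t) g calibrated on outgroup divergence d, split time t (years)
and generation time g (years).

Alignment columns containing any gap or ambiguous base within the
analysed sample are excluded entirely, and the per-site denominators use
the count of remaining complete columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .simulate import HaplotypeAlignment


# ---------------------------------------------------------------------------
# combinatorial constants
# ---------------------------------------------------------------------------

def harmonic(n: int, power: int = 1) -> float:
    """a_n = sum_{i=1}^{n} 1/i^power, computed by direct stable summation."""
    return float(np.sum(1.0 / np.arange(1, n + 1, dtype=float) ** power))


def _tajima_constants(n: int) -> tuple[float, float]:
    a1 = harmonic(n - 1)
    a2 = harmonic(n - 1, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return e1, e2


def _fu_li_dstar_constants(n: int) -> tuple[float, float]:
    """u* and v* of Fu & Li's D*, with the published correction."""
    a = harmonic(n - 1)
    b = harmonic(n - 1, 2)
    an1 = a + 1.0 / n
    if n == 2:
        c = 1.0
    else:
        c = 2.0 * (n * a - 2.0 * (n - 1)) / ((n - 1) * (n - 2))
    d = (c + (n - 2) / ((n - 1) ** 2)
         + (2.0 / (n - 1)) * (1.5 - (2.0 * an1 - 3.0) / (n - 2) - 1.0 / n))
    v = (((n / (n - 1.0)) ** 2) * b + a * a * d
         - 2.0 * (n * a * (a + 1.0)) / ((n - 1.0) ** 2)) / (a * a + b)
    u = (n / (n - 1.0)) * (a - n / (n - 1.0)) - v
    return u, v


# ---------------------------------------------------------------------------
# alignment handling
# ---------------------------------------------------------------------------

_VALID = frozenset("ACGT")


def _matrix(sequences: Sequence[str]) -> np.ndarray:
    """Complete-case column matrix: columns with any gap/N are dropped."""
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    arr = np.array([list(s.upper()) for s in sequences])
    keep = np.all(np.isin(arr, list(_VALID)), axis=0)
    return arr[:, keep]


def _pop_sequences(data, population: str | None) -> list[str]:
    if isinstance(data, HaplotypeAlignment):
        if population is None:
            return [s for s, lab in zip(data.sequences, data.labels)
                    if lab != data.outgroup_label]
        return data.sequences_for(population)
    return list(data)


def _site_counts(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(minor counts, allele number) per segregating column."""
    n = mat.shape[0]
    minor = []
    for col in mat.T:
        _, cnt = np.unique(col, return_counts=True)
        if len(cnt) == 2:
            minor.append(int(cnt.min()))
        elif len(cnt) > 2:
            # infinite-sites data should not produce these; count the
            # rarest allele so the site still registers as segregating
            minor.append(int(np.sort(cnt)[:-1].sum()))
    return np.asarray(minor, dtype=int), np.asarray([n] * len(minor))


def segregating_sites(data, population: str | None = None) -> int:
    mat = _matrix(_pop_sequences(data, population))
    return int(np.sum([len(np.unique(col)) > 1 for col in mat.T]))


# ---------------------------------------------------------------------------
# core estimators
# ---------------------------------------------------------------------------

def watterson_theta(S: int, n: int, length: int) -> float:
    """Watterson's estimator per site: S / (a_n * L)."""
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    if length <= 0:
        raise ValueError("length must be positive")
    if S < 0:
        raise ValueError("S must be non-negative")
    return S / (harmonic(n - 1) * length)


def nucleotide_diversity(data, population: str | None = None) -> float:
    """Mean pairwise difference per complete-case site."""
    mat = _matrix(_pop_sequences(data, population))
    n, L = mat.shape
    if L == 0:
        return 0.0
    total = 0.0
    for col in mat.T:
        _, cnt = np.unique(col, return_counts=True)
        total += (n * n - np.sum(cnt.astype(float) ** 2)) / 2.0
    return total / (n * (n - 1) / 2.0) / L


def _pi_total_from_minor(minor: np.ndarray, n: int) -> float:
    """Sum over sites of pairwise-difference fractions (biallelic sites)."""
    minor = np.asarray(minor, dtype=float)
    return float(np.sum(minor * (n - minor)) / (n * (n - 1) / 2.0))


def tajimas_d_from_counts(S: int, pi_total: float, n: int) -> float:
    """Tajima's D from the segregating-site count and total mean pairwise
    differences; NaN when S = 0 (statistic undefined)."""
    if S == 0:
        return math.nan
    a1 = harmonic(n - 1)
    e1, e2 = _tajima_constants(n)
    return (pi_total - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def fu_li_dstar_from_counts(S: int, singletons: int, n: int) -> float:
    """Fu & Li's D* from total mutations and folded singleton count."""
    if S == 0:
        return math.nan
    a = harmonic(n - 1)
    u, v = _fu_li_dstar_constants(n)
    num = (n / (n - 1.0)) * S - a * singletons
    return num / math.sqrt(u * S + v * S * S)


def tajimas_d(data, population: str | None = None) -> float:
    mat = _matrix(_pop_sequences(data, population))
    minor, _ = _site_counts(mat)
    n = mat.shape[0]
    return tajimas_d_from_counts(len(minor), _pi_total_from_minor(minor, n), n)


def fu_li_dstar(data, population: str | None = None) -> float:
    mat = _matrix(_pop_sequences(data, population))
    minor, _ = _site_counts(mat)
    n = mat.shape[0]
    return fu_li_dstar_from_counts(len(minor), int(np.sum(minor == 1)), n)


# ---------------------------------------------------------------------------
# effective size and time scales
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvolutionaryRateParams:
    """Mutation-rate calibration: mu = (d / 2t) * g."""

    d: float      # sequence divergence to the outgroup (proportion)
    t: float      # outgroup divergence time, years
    g: float      # generation time, years

    def __post_init__(self) -> None:
        if min(self.d, self.t, self.g) <= 0:
            raise ValueError("d, t and g must all be positive")

    @property
    def mu(self) -> float:
        """Per-generation per-site mutation rate."""
        return (self.d / (2.0 * self.t)) * self.g


PAN_RATES = EvolutionaryRateParams(d=0.0135, t=6e6, g=20.0)


def effective_size(theta_w: float, rates: EvolutionaryRateParams) -> float:
    """Ne = theta_w / (4 mu)."""
    if theta_w < 0:
        raise ValueError("theta_w must be non-negative")
    return theta_w / (4.0 * rates.mu)


def round_ne(ne: float) -> int:
    """Report-style rounding of Ne to the nearest 100."""
    return int(round(ne / 100.0)) * 100


def mean_coalescent_time(ne: float, g: float) -> float:
    """Average pairwise coalescent time ~ 4 Ne generations, in years."""
    if ne < 0 or g <= 0:
        raise ValueError("ne must be >= 0 and g > 0")
    return 4.0 * ne * g


# ---------------------------------------------------------------------------
# per-locus and pooled summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusSummary:
    name: str
    n: int
    length: int
    S: int
    pi: float          # per site
    theta_w: float     # per site
    tajima_d: float    # NaN when S == 0
    fu_li_dstar: float
    singletons: int = 0
    pi_total: float = 0.0


def locus_summary(data, population: str | None = None,
                  name: str = "locus") -> LocusSummary:
    mat = _matrix(_pop_sequences(data, population))
    n, L = mat.shape
    minor, _ = _site_counts(mat)
    S = len(minor)
    pi_total = _pi_total_from_minor(minor, n)
    singles = int(np.sum(minor == 1))
    return LocusSummary(
        name=name, n=n, length=L, S=S,
        pi=pi_total / L if L else 0.0,
        theta_w=watterson_theta(S, n, L) if L else 0.0,
        tajima_d=tajimas_d_from_counts(S, pi_total, n),
        fu_li_dstar=fu_li_dstar_from_counts(S, singles, n),
        singletons=singles, pi_total=pi_total)


def pooled_summary(summaries: Iterable[LocusSummary],
                   name: str = "pooled") -> LocusSummary:
    """Multi-locus pooled row: summed S and length, length-weighted pi and
    theta_w, D and D* computed on the concatenated totals (all loci must
    share the sample size)."""
    summaries = list(summaries)
    ns = {s.n for s in summaries}
    if len(ns) != 1:
        raise ValueError("pooled summary requires a common sample size")
    n = ns.pop()
    S = sum(s.S for s in summaries)
    L = sum(s.length for s in summaries)
    pi_total = sum(s.pi_total for s in summaries)
    singles = sum(s.singletons for s in summaries)
    return LocusSummary(
        name=name, n=n, length=L, S=S,
        pi=pi_total / L if L else 0.0,
        theta_w=watterson_theta(S, n, L) if L else 0.0,
        tajima_d=tajimas_d_from_counts(S, pi_total, n),
        fu_li_dstar=fu_li_dstar_from_counts(S, singles, n),
        singletons=singles, pi_total=pi_total)


def summary_table(rows: dict[str, LocusSummary],
                  rates: EvolutionaryRateParams | None = PAN_RATES):
    """Diversity-table DataFrame (percentages to 2 decimals, Ne to the
    nearest 100), one row per population."""
    import pandas as pd

    out = []
    for popname, s in rows.items():
        rec = {"population": popname, "n": s.n, "length": s.length, "S": s.S,
               "pi_pct": round(100 * s.pi, 2),
               "theta_w_pct": round(100 * s.theta_w, 2),
               "tajima_d": round(s.tajima_d, 2),
               "fu_li_dstar": round(s.fu_li_dstar, 2)}
        if rates is not None:
            rec["Ne"] = round_ne(effective_size(s.theta_w, rates))
        out.append(rec)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# differentiation
# ---------------------------------------------------------------------------

def pairwise_fst(counts1, n1, counts2, n2, method: str = "hudson") -> float:
    """Fst from pooled biallelic per-site derived-allele counts.

    hudson: 1 - Hw/Hb combined across sites as a ratio of averages, with
    Hw the mean of the two within-population heterozygosities and
    Hb = p1(1-p2) + p2(1-p1).  weir-cockerham: the 1984 variance-component
    estimator, also as a ratio of sums.
    """
    c1 = np.asarray(counts1, dtype=float)
    c2 = np.asarray(counts2, dtype=float)
    m1 = np.broadcast_to(np.asarray(n1, dtype=float), c1.shape)
    m2 = np.broadcast_to(np.asarray(n2, dtype=float), c2.shape)
    if c1.size == 0:
        raise ValueError("no usable sites")
    p1, p2 = c1 / m1, c2 / m2
    if method == "hudson":
        hw = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2.0
        hb = p1 * (1 - p2) + p2 * (1 - p1)
        usable = hb > 0
        if not usable.any():
            raise ValueError("no polymorphic sites across the pair")
        fst = 1.0 - hw[usable].sum() / hb[usable].sum()
    elif method == "weir-cockerham":
        nbar = (m1 + m2) / 2.0
        nc = (2 * nbar - (m1 ** 2 + m2 ** 2) / (2 * nbar))
        pbar = (m1 * p1 + m2 * p2) / (2 * nbar)
        s2 = (m1 * (p1 - pbar) ** 2 + m2 * (p2 - pbar) ** 2) / nbar
        hbar = (m1 * 2 * p1 * (1 - p1) * m1 / (m1 - 1)
                + m2 * 2 * p2 * (1 - p2) * m2 / (m2 - 1)) / (2 * nbar)
        r = 2.0
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
        denom = (a + b + c).sum()
        if denom == 0:
            raise ValueError("no polymorphic sites across the pair")
        fst = a.sum() / denom
    else:
        raise ValueError(f"unknown Fst method {method!r}")
    return float(min(fst, 1.0))


def _biallelic_counts(alignments: Iterable[HaplotypeAlignment],
                      pop_a: str, pop_b: str):
    """Per-site allele counts of a reference allele shared by both pops."""
    ca, cb, na, nb = [], [], [], []
    for aln in alignments:
        seq_a = np.array([list(s) for s in aln.sequences_for(pop_a)])
        seq_b = np.array([list(s) for s in aln.sequences_for(pop_b)])
        for j in range(aln.locus_length):
            col_a, col_b = seq_a[:, j], seq_b[:, j]
            col = np.concatenate([col_a, col_b])
            alleles = [x for x in np.unique(col) if x in _VALID]
            if len(alleles) != 2 or not set(col) <= _VALID:
                continue
            ref = alleles[0]
            ca.append(int(np.sum(col_a == ref)))
            cb.append(int(np.sum(col_b == ref)))
            na.append(len(col_a))
            nb.append(len(col_b))
    return (np.array(ca), np.array(na), np.array(cb), np.array(nb))


def fst_between(alignments: Iterable[HaplotypeAlignment], pop_a: str,
                pop_b: str, method: str = "hudson") -> float:
    """Fst between two labeled populations, SNPs pooled across loci."""
    ca, na, cb, nb = _biallelic_counts(list(alignments), pop_a, pop_b)
    return pairwise_fst(ca, na, cb, nb, method=method)


def fst_matrix(alignments, populations: Sequence[str],
               method: str = "hudson"):
    """Lower-triangular pairwise-Fst DataFrame across populations."""
    import pandas as pd

    alignments = list(alignments)
    mat = pd.DataFrame(np.nan, index=populations, columns=populations)
    for i, a in enumerate(populations):
        for b in populations[:i]:
            mat.loc[a, b] = round(fst_between(alignments, a, b,
                                              method=method), 2)
    return mat


# ---------------------------------------------------------------------------
# allele-sharing site classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteClassCounts:
    """Counts of polarized biallelic sites by sharing pattern between two
    groups (a, b), with derived state read off the outgroup."""

    a_poly_b_fixed_derived: int = 0
    b_poly_a_fixed_derived: int = 0
    both_poly: int = 0
    a_fixed_derived_b_ancestral: int = 0
    b_fixed_derived_a_ancestral: int = 0

    @property
    def total(self) -> int:
        return (self.a_poly_b_fixed_derived + self.b_poly_a_fixed_derived
                + self.both_poly + self.a_fixed_derived_b_ancestral
                + self.b_fixed_derived_a_ancestral)


def classify_shared_sites(aln: HaplotypeAlignment, pop_a: str,
                          pop_b: str) -> SiteClassCounts:
    """Assign each polarized biallelic site to one of five sharing
    categories; sites where the outgroup carries a third allele, or where
    the polymorphism is private with the other group fixed ancestral, are
    skipped."""
    if aln.outgroup_label is None:
        raise ValueError("classification needs an outgroup to polarize sites")
    out = aln.outgroup_sequence
    seq_a = np.array([list(s) for s in aln.sequences_for(pop_a)])
    seq_b = np.array([list(s) for s in aln.sequences_for(pop_b)])
    k = dict.fromkeys(
        ("a_poly_b_fixed_derived", "b_poly_a_fixed_derived", "both_poly",
         "a_fixed_derived_b_ancestral", "b_fixed_derived_a_ancestral"), 0)
    for j in range(aln.locus_length):
        col_a, col_b, anc = seq_a[:, j], seq_b[:, j], out[j]
        col = np.concatenate([col_a, col_b])
        if not set(col) <= _VALID or anc not in _VALID:
            continue
        alleles = set(col)
        if len(alleles) > 2 or (len(alleles) == 1 and anc in alleles):
            continue
        if anc not in alleles | set() and len(alleles) == 2:
            continue  # outgroup carries a third allele: cannot polarize
        a_set, b_set = set(col_a), set(col_b)
        a_poly, b_poly = len(a_set) > 1, len(b_set) > 1
        if a_poly and b_poly:
            k["both_poly"] += 1
        elif a_poly and not b_poly:
            if col_b[0] != anc:
                k["a_poly_b_fixed_derived"] += 1
        elif b_poly and not a_poly:
            if col_a[0] != anc:
                k["b_poly_a_fixed_derived"] += 1
        else:  # both fixed, for different alleles
            if col_a[0] != anc and col_b[0] == anc:
                k["a_fixed_derived_b_ancestral"] += 1
            elif col_b[0] != anc and col_a[0] == anc:
                k["b_fixed_derived_a_ancestral"] += 1
    return SiteClassCounts(**k)
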