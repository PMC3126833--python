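"""End-to-end orchestration: simulate -> call -> stats -> neutrality -> monophyly.

A run is described by a plain YAML config (stage list, global seed,
per-stage parameter blocks).  Outputs are plain-text tables plus a
manifest recording the seed, parameters and SHA-256 checksums of every
file written, so identical configs reproduce identical runs byte for
byte.  Per-locus seeds are drawn from a master generator seeded with the
global seed, so any locus can be regenerated independently.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import monophyly as mono
from . import neutrality as neut
from . import popgen, simulate, snp_calling

log = logging.getLogger("pansort")

STAGES = ("simulate", "callsnps", "stats", "neutrality", "monophyly")

# study-scale defaults: 15 unlinked ~10 kb loci, 40 chromosomes per
# population, per-site theta of 1e-3 (the observed autosomal range is
# roughly 0.8e-3 to 3.2e-3) and a comparable per-site rho
DEFAULTS: dict = {
    "simulate": {"model": "split", "loci": 15, "locus_length": 10_000,
                 "n_per_pop": [40, 40], "n_samples": 40,
                 "theta_per_site": 1e-3, "rho_per_site": 8e-4,
                 "split_time": 0.5, "growth_rate": 0.0},
    "callsnps": {"mean_coverage": 20.0, "min_depth": 8, "maf": 0.15,
                 "nqs_core": 20, "nqs_flank": 15, "regions": 2},
    "stats": {"divergence": 0.0135, "t_div": 6e6, "generation": 20.0},
    "neutrality": {"reps": 1000, "population": None},
    "monophyly": {"burnin": 0.10},
}


@dataclass
class RunConfig:
    stages: list[str]
    outdir: Path
    seed: int = 0
    log_level: str = "INFO"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}")
        self.outdir = Path(self.outdir)

    def stage_params(self, stage: str) -> dict:
        merged = dict(DEFAULTS.get(stage, {}))
        merged.update(self.params.get(stage, {}))
        return merged


def load_config(path) -> RunConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    stages = raw.pop("stages", list(STAGES))
    outdir = raw.pop("outdir", "pansort_out")
    seed = int(raw.pop("seed", 0))
    log_level = raw.pop("log_level", "INFO")
    return RunConfig(stages=stages, outdir=outdir, seed=seed,
                     log_level=log_level, params=raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages in dependency order; returns (and
    writes) the run manifest."""
    logging.basicConfig(level=config.log_level)
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(config.seed)
    written: list[Path] = []
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}

    alignments: list[simulate.HaplotypeAlignment] = []
    sim_p = config.stage_params("simulate")
    if "simulate" in config.stages:
        log.info("simulating %d loci (%s model)", sim_p["loci"], sim_p["model"])
        theta = sim_p["theta_per_site"] * sim_p["locus_length"]
        rho = sim_p["rho_per_site"] * sim_p["locus_length"]
        for i in range(sim_p["loci"]):
            locus_seed = int(master.integers(2 ** 31))
            if sim_p["model"] == "split":
                params = simulate.SplitModelParams(
                    n_per_pop=tuple(sim_p["n_per_pop"]),
                    split_time=sim_p["split_time"])
                aln = simulate.simulate_split(
                    params, theta, locus_seed,
                    locus_length=sim_p["locus_length"])
            elif sim_p["model"] == "neutral":
                params = simulate.CoalescentParams(
                    n_samples=sim_p["n_samples"],
                    locus_length=sim_p["locus_length"], theta=theta,
                    rho=rho, growth_rate=sim_p["growth_rate"])
                aln = simulate.simulate_locus(params, locus_seed)
            else:
                raise ValueError(f"unknown model {sim_p['model']!r}")
            alignments.append(aln)
            fa = out / f"locus_{i:02d}.fasta"
            simulate.write_fasta(aln, fa)
            written.append(fa)
        popmap = out / "popmap.tsv"
        with open(popmap, "w") as fh:
            for lab, pop in alignments[0].pop_map.items():
                fh.write(f"{lab}\t{pop}\n")
        written.append(popmap)
        if alignments[0].gene_tree:
            trees = out / "gene_trees.nwk"
            with open(trees, "w") as fh:
                for aln in alignments:
                    fh.write(aln.gene_tree + "\n")
            written.append(trees)
        manifest["stages"]["simulate"] = sim_p

    if "callsnps" in config.stages:
        if not alignments:
            raise ValueError("callsnps stage needs simulated loci")
        cp = config.stage_params("callsnps")
        cfg = snp_calling.CallerConfig(
            min_depth=cp["min_depth"], maf_threshold=cp["maf"],
            nqs_core=cp["nqs_core"], nqs_flank=cp["nqs_flank"])
        calls_path = out / "snp_calls.tsv"
        with open(calls_path, "w") as fh:
            fh.write("CHROM\tPOS\tREF\tALT\tMAF\tDEPTH\tSTATUS\n")
            for i, aln in enumerate(alignments[:cp["regions"]]):
                rcfg = simulate.ReadSimConfig(
                    mean_coverage=cp["mean_coverage"],
                    seed=int(master.integers(2 ** 31)))
                pile = simulate.simulate_reads(
                    (aln.sequences[0], aln.sequences[1]), rcfg)
                report = snp_calling.call_region(pile, cfg)
                for c in report.heterozygous_calls:
                    fh.write(f"locus_{i:02d}\t{c.position + 1}\t"
                             f"{c.major_allele}\t{c.minor_allele}\t"
                             f"{c.maf:.4f}\t{c.depth_after_filters}\thet\n")
        written.append(calls_path)
        manifest["stages"]["callsnps"] = cp

    if "stats" in config.stages:
        if not alignments:
            raise ValueError("stats stage needs simulated loci")
        sp = config.stage_params("stats")
        rates = popgen.EvolutionaryRateParams(
            d=sp["divergence"], t=sp["t_div"], g=sp["generation"])
        pops = alignments[0].populations
        rows = {}
        for pop in pops:
            summaries = [popgen.locus_summary(a, pop, name=f"locus_{i:02d}")
                         for i, a in enumerate(alignments)]
            rows[pop] = popgen.pooled_summary(summaries, name=pop)
        table = popgen.summary_table(rows, rates)
        t1 = out / "diversity_table.tsv"
        table.to_csv(t1, sep="\t", index=False)
        written.append(t1)
        if len(pops) >= 2:
            fst = popgen.fst_matrix(alignments, pops)
            t3 = out / "fst_matrix.tsv"
            fst.to_csv(t3, sep="\t")
            written.append(t3)
            cls = popgen.classify_shared_sites(alignments[0], pops[0], pops[1])
            t2s = out / "site_classes.tsv"
            with open(t2s, "w") as fh:
                fh.write("category\tcount\n")
                for name in ("a_poly_b_fixed_derived", "b_poly_a_fixed_derived",
                             "both_poly", "a_fixed_derived_b_ancestral",
                             "b_fixed_derived_a_ancestral"):
                    fh.write(f"{name}\t{getattr(cls, name)}\n")
            written.append(t2s)
        manifest["stages"]["stats"] = sp

    if "neutrality" in config.stages:
        if not alignments:
            raise ValueError("neutrality stage needs simulated loci")
        np_ = config.stage_params("neutrality")
        pop = np_["population"] or alignments[0].populations[0]
        summaries = [popgen.locus_summary(a, pop) for a in alignments]
        theta_locus = [max(s.theta_w, 1e-6) * s.length for s in summaries]
        # per-locus recombination estimates: a log-normal spread around the
        # configured per-site rate, mimicking map-based locus variation
        rho_locus = [sim_p["rho_per_site"] * s.length
                     * float(np.exp(master.normal(0.0, 0.5)))
                     for s in summaries]
        ncfg = simulate.sample_null_hyperparams(
            theta_locus, rho_locus,
            loci=[(s.n, s.length) for s in summaries],
            reps=np_["reps"], seed=int(master.integers(2 ** 31)))
        obs = neut.observed_summary(alignments, pop)
        fit = neut.composite_fit(obs, ncfg)
        nj = out / "neutrality.json"
        with open(nj, "w") as fh:
            json.dump({"population": pop, "seed": ncfg.seed,
                       "reps": ncfg.reps, "C": fit.C,
                       "fit_pvalue": fit.fit_pvalue,
                       "per_stat_pvalues": fit.per_stat_pvalues}, fh,
                      indent=2)
        written.append(nj)
        manifest["stages"]["neutrality"] = {**np_, "population": pop}

    if "monophyly" in config.stages:
        if not alignments or not alignments[0].gene_tree:
            raise ValueError("monophyly stage needs split-model gene trees")
        mp = config.stage_params("monophyly")
        import dendropy

        tns = dendropy.TaxonNamespace()
        trees = [dendropy.Tree.get(data=a.gene_tree, schema="newick",
                                   taxon_namespace=tns,
                                   preserve_underscores=True)
                 for a in alignments]
        # graft the outgroup above each gene-tree root for rooting
        for t in trees:
            new_root = dendropy.Node()
            old = t.seed_node
            new_root.add_child(old)
            og = dendropy.Node(
                taxon=tns.require_taxon("outgroup"))
            new_root.add_child(og)
            t.seed_node = new_root
        sample = mono.TreeSample(trees=trees,
                                 pop_map=alignments[0].pop_map,
                                 outgroup_label="outgroup")
        pops = alignments[0].populations
        t2 = out / "monophyly_table.tsv"
        with open(t2, "w") as fh:
            fh.write("group\tposterior\tclassification\n")
            per_tree = []
            for i, tree in enumerate(trees):
                single = mono.TreeSample(trees=[tree],
                                         pop_map=alignments[0].pop_map,
                                         outgroup_label="outgroup")
                rec = mono.reciprocal_monophyly(single, pops[0], pops[1])
                per_tree.append((f"locus_{i:02d}", rec.posterior_probability))
            rec = mono.reciprocal_monophyly(sample, pops[0], pops[1])
            fh.write(f"reciprocal({pops[0]},{pops[1]})\t"
                     f"{rec.posterior_probability:.3f}\t{rec.classification}\n")
            for pop in pops:
                rep = mono.posterior_monophyly(sample, pop)
                fh.write(f"{pop}\t{rep.posterior_probability:.3f}\t"
                         f"{rep.classification}\n")
        written.append(t2)
        cons = mono.majority_consensus(sample)
        cn = out / "consensus.nwk"
        cn.write_text(cons.as_string(schema="newick",
                                     suppress_rooting=True))
        written.append(cn)
        manifest["stages"]["monophyly"] = mp

    manifest["outputs"] = {p.name: _sha256(p) for p in written}
    mpath = out / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("wrote %d outputs to %s", len(written), out)
    return manifest
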