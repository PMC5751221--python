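"""End-to-end orchestration: trim -> branch lengths -> conservation ->
selection -> pair scans -> null calibration -> integration.

Each stage writes its outputs (TSV/JSON/FASTA/Newick) under the run
directory together with a checkpoint carrying a hash of the configuration;
re-running with the same configuration resumes after the last completed
stage, while any configuration change invalidates downstream checkpoints.
All randomness flows from the configured seed, so two identical runs
produce byte-identical outputs.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import conservation, coevolution, integration, phylo_engine, seq_io
from . import selection as sel
from .trees import Tree

log = logging.getLogger("melcoev")

STAGES = ("trim", "branchlen", "conserve", "select", "coevscan",
          "calibrate", "integrate")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Pipeline configuration (YAML/JSON-loadable)."""

    gene_fastas: dict[str, str]
    tree_file: str
    out_dir: str
    percentiles: tuple[float, ...] = (0.90, 0.95, 0.975)
    null_nsites: int = 200
    null_pairs: int | None = None       # subsample of null site pairs
    seed: int = 1
    fdr_level: float = 0.05
    max_ambiguity_fraction: float = 0.2
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        for p in self.percentiles:
            if not 0.0 < p < 1.0:
                raise ConfigError(f"percentile {p} outside (0, 1)")
        if not 0.0 < self.fdr_level < 1.0:
            raise ConfigError("FDR level must be in (0, 1)")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _pair_seed(base: int, index: int) -> int:
    return (base * 100003 + 7919 * index + 13) % (2**31)


class PipelineRun:
    """Stage runner with checkpointing over a run directory."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        (self.out / "checkpoints").mkdir(exist_ok=True)
        self.genes = sorted(config.gene_fastas)
        self.manifest: dict = {"config_hash": config.content_hash(),
                               "stages": {}, "failed": None}

    # -- checkpoint helpers ---------------------------------------------
    def _ckpt(self, stage: str) -> Path:
        return self.out / "checkpoints" / f"{stage}.json"

    def _done(self, stage: str) -> bool:
        path = self._ckpt(stage)
        if not path.exists():
            return False
        with open(path) as fh:
            return json.load(fh).get("hash") == self.config.content_hash()

    def _mark(self, stage: str) -> None:
        with open(self._ckpt(stage), "w") as fh:
            json.dump({"hash": self.config.content_hash()}, fh)
        self.manifest["stages"][stage] = "done"

    # -- stages ----------------------------------------------------------
    def run(self) -> dict:
        try:
            self.topology = Tree.read(self.config.tree_file)
            self.raw = {g: seq_io.read_alignment(p, g)
                        for g, p in sorted(self.config.gene_fastas.items())}
            for stage in STAGES:
                if stage not in self.config.stages:
                    continue
                getattr(self, f"stage_{stage}")()
        except Exception as exc:
            self.manifest["failed"] = {"stage": getattr(self, "_stage", "?"),
                                       "error": str(exc)}
            self._write_manifest()
            raise
        self._write_manifest()
        return self.manifest

    def _write_manifest(self) -> None:
        self.manifest["seed"] = self.config.seed
        self.manifest["percentiles"] = list(self.config.percentiles)
        self.manifest["k_coev"] = coevolution.K_COEV
        self.manifest["k_indep"] = coevolution.K_INDEP
        with open(self.out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)

    def stage_trim(self) -> None:
        self._stage = "trim"
        self.trimmed: dict[str, seq_io.GeneAlignment] = {}
        if self._done("trim"):
            for g in self.genes:
                aln = seq_io.read_alignment(self.out / f"{g}.trimmed.fasta", g)
                prov = pd.read_csv(self.out / f"{g}.provenance.tsv", sep="\t")
                aln.orig_columns = prov["original_column"].to_numpy()
                aln.is_trimmed = True
                self.trimmed[g] = aln
            return
        for g in self.genes:
            aln = seq_io.trim_alignment(
                self.raw[g], identity_cutoff=1.0,
                max_ambiguity_fraction=self.config.max_ambiguity_fraction,
                codon_mode=True)
            seq_io.write_alignment(aln, self.out / f"{g}.trimmed.fasta")
            seq_io.write_provenance(aln, self.out / f"{g}.provenance.tsv")
            self.trimmed[g] = aln
            log.info("trim %s: %d -> %d columns", g, self.raw[g].width, aln.width)
        self._mark("trim")

    def stage_branchlen(self) -> None:
        self._stage = "branchlen"
        self.gene_models: dict[str, phylo_engine.PhyloModel] = {}
        meta_path = self.out / "gene_models.json"
        if self._done("branchlen"):
            with open(meta_path) as fh:
                meta = json.load(fh)
            for g in self.genes:
                tree = Tree.from_newick(
                    (self.out / f"{g}.tree.nwk").read_text())
                tree = self._renumber(tree)
                self.gene_models[g] = phylo_engine.PhyloModel(
                    tree, meta[g]["kappa"], np.array(meta[g]["freqs"]),
                    meta[g]["alpha"])
            return
        meta = {}
        for g in self.genes:
            model = phylo_engine.optimize_branch_lengths(
                self.trimmed[g], self.topology)
            self.gene_models[g] = model
            model.tree.write(self.out / f"{g}.tree.nwk")
            meta[g] = {"kappa": model.kappa, "alpha": model.gamma_shape,
                       "freqs": model.base_freqs.tolist(),
                       "loglik": model.loglik}
            log.info("branchlen %s: lnL=%.2f kappa=%.2f", g,
                     model.loglik, model.kappa)
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
        self._mark("branchlen")

    def _renumber(self, tree: Tree) -> Tree:
        """Map a re-read tree onto the shared topology's node numbering."""
        if tree.leaf_names == self.topology.leaf_names:
            sets_t = tree.leafsets()
            sets_o = self.topology.leafsets()
            by_set = {s: v for v, s in sets_t.items()}
            if set(sets_o.values()) == set(by_set):
                blen = np.zeros(self.topology.n_nodes)
                for v, s in sets_o.items():
                    blen[v] = tree.blen[by_set[s]]
                return self.topology.with_blen(blen)
        return tree

    def stage_conserve(self) -> None:
        self._stage = "conserve"
        if self._done("conserve"):
            return
        summaries = {}
        for g in self.genes:
            prof = conservation.conservation_profile(self.trimmed[g])
            conservation.write_profile_tsv(
                prof, self.out / f"{g}.conservation.tsv")
            summaries[g] = json.loads(conservation.summary_json(prof))
        with open(self.out / "conservation.json", "w") as fh:
            json.dump(summaries, fh, indent=2, sort_keys=True)
        self._mark("conserve")

    def stage_select(self) -> None:
        self._stage = "select"
        self.calls: dict[str, list[sel.SiteSelectionCall]] = {}
        if self._done("select"):
            for g in self.genes:
                self.calls[g] = _read_calls(self.out / f"{g}.selection.tsv")
            return
        for g in self.genes:
            model = self.gene_models[g]
            cols = sel.extract_codon_columns(
                self.trimmed[g].subset_species(model.tree.leaf_names))
            indices = [self.trimmed[g].codon_of_column(3 * k)
                       for k in range(len(cols))]
            engine = sel.CodonEngine(model.tree, kappa=model.kappa)
            calls = sel.analyze_gene(cols, model.tree, engine=engine,
                                     fdr_level=self.config.fdr_level,
                                     codon_indices=indices)
            self.calls[g] = calls
            _write_calls(calls, self.out / f"{g}.selection.tsv")
            with open(self.out / f"{g}.selection.json", "w") as fh:
                json.dump(sel.selection_summary(calls), fh, indent=2)
            log.info("select %s: %s", g, sel.selection_summary(calls))
        self._mark("select")

    def _gene_pairs(self) -> list[tuple[str, str]]:
        return list(combinations(self.genes, 2))

    def stage_coevscan(self) -> None:
        self._stage = "coevscan"
        self.scans: dict[tuple[str, str], pd.DataFrame] = {}
        self.pair_trees: dict[tuple[str, str], Tree] = {}
        done = self._done("coevscan")
        for idx, (ga, gb) in enumerate(self._gene_pairs()):
            scan_path = self.out / f"scan.{ga}-{gb}.tsv.gz"
            tree_path = self.out / f"pair.{ga}-{gb}.tree.nwk"
            if done and scan_path.exists():
                with gzip.open(scan_path, "rt") as fh:
                    self.scans[(ga, gb)] = pd.read_csv(fh, sep="\t",
                                                       keep_default_na=False,
                                                       na_values=["nan"])
                self.pair_trees[(ga, gb)] = self._renumber(
                    Tree.from_newick(tree_path.read_text()))
                continue
            paired = seq_io.pair_genes(self.trimmed[ga], self.trimmed[gb])
            concat = seq_io.GeneAlignment(
                gene_name=f"{ga}+{gb}", species=paired.shared_species,
                sequences=np.hstack([paired.gene_a.sequences,
                                     paired.gene_b.sequences]))
            model = phylo_engine.optimize_branch_lengths(concat, self.topology)
            tree = model.tree
            tree.write(tree_path)
            self.pair_trees[(ga, gb)] = tree
            engine = coevolution.CoevEngine(tree)
            scan = coevolution.scan_gene_pair(paired, tree, engine)
            with gzip.open(scan_path, "wt") as fh:
                scan.to_csv(fh, sep="\t", index=False, float_format="%.6g")
            self.scans[(ga, gb)] = scan
            log.info("coevscan %s-%s: %d pairs", ga, gb, len(scan))
        self._mark("coevscan")

    def stage_calibrate(self) -> None:
        self._stage = "calibrate"
        self.calibrations: dict[tuple[str, str], coevolution.NullCalibration] = {}
        done = self._done("calibrate")
        for idx, (ga, gb) in enumerate(self._gene_pairs()):
            path = self.out / f"calibration.{ga}-{gb}.json"
            if done and path.exists():
                with open(path) as fh:
                    payload = json.load(fh)
                self.calibrations[(ga, gb)] = coevolution.NullCalibration(
                    sample=np.array([]), thresholds=payload["thresholds"],
                    seed=payload["seed"], nsites=payload["nsites"])
                continue
            tree = self.pair_trees[(ga, gb)]
            calib = coevolution.calibrate_null(
                tree, nsites=self.config.null_nsites,
                seed=_pair_seed(self.config.seed, idx),
                n_pairs=self.config.null_pairs,
                percentiles=[100 * p for p in self.config.percentiles])
            calib.to_json(path)
            self.calibrations[(ga, gb)] = calib
        self._mark("calibrate")

    def stage_integrate(self) -> None:
        self._stage = "integrate"
        if self._done("integrate"):
            return
        lengths = {g: self.trimmed[g].width for g in self.genes}
        offsets = {g: self.trimmed[g].frame_offset for g in self.genes}
        mean_blen = np.mean(
            [self.gene_models[g].tree.blen for g in self.genes], axis=0)
        common_tree = self.topology.with_blen(mean_blen)
        n_scanned = {g: 0 for g in self.genes}
        for (ga, gb), df in self.scans.items():
            n_scanned[ga] += len(df)
            n_scanned[gb] += len(df)
        for p in self.config.percentiles:
            pct = 100 * p
            tag = f"{pct:g}"
            thresholds = {key: cal.threshold(pct)
                          for key, cal in self.calibrations.items()}
            table2 = integration.count_coevolving_pairs(self.scans, thresholds)
            table2.to_csv(self.out / f"table2.p{tag}.tsv", sep="\t",
                          float_format="%.6g")
            response = integration.select_response_pairs(
                self.scans, self.calls, thresholds, offsets)
            response.to_csv(self.out / f"response_pairs.p{tag}.tsv",
                            sep="\t", index=False, float_format="%.6g")
            stats = integration.distinct_site_stats(response, lengths)
            partner = integration.partner_pair_counts(response, self.genes)
            pair_labels = integration.gene_vs_rest_chisq(
                stats["n_pairs"].to_dict(), n_scanned,
                alpha=self.config.fdr_level)["label"]
            site_labels = integration.gene_vs_rest_chisq(
                stats["n_distinct_sites"].to_dict(), lengths,
                alpha=self.config.fdr_level)["label"]
            table1 = integration.build_table1(partner, stats, pair_labels,
                                              site_labels)
            overlap = integration.branch_overlap_pct(
                response, self.calls, self.trimmed, common_tree)
            table1["pct_branches"] = pd.Series(overlap)
            table1.to_csv(self.out / f"table1.p{tag}.tsv", sep="\t",
                          float_format="%.6g")
            metrics = pd.DataFrame({
                "n_pairs": stats["n_pairs"],
                "n_distinct_sites": stats["n_distinct_sites"],
                "pct_branches": pd.Series(overlap),
            })
            try:
                ord_res = integration.pca_influence(metrics)
                out = ord_res.scores.copy()
                out.columns = [f"score_{c}" for c in out.columns]
                out.to_csv(self.out / f"influence_pca.p{tag}.tsv", sep="\t",
                           float_format="%.6g")
                with open(self.out / f"influence_pca.p{tag}.json", "w") as fh:
                    json.dump({
                        "variables": ord_res.variables,
                        "eigenvalues": ord_res.eigenvalues.tolist(),
                        "explained_pct": ord_res.explained_pct.tolist(),
                        "retained": ord_res.retained.tolist(),
                        "loadings": ord_res.loadings.tolist(),
                    }, fh, indent=2)
            except integration.IntegrationError as exc:
                log.warning("PCA skipped at p%s: %s", tag, exc)
        self._mark("integrate")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns the run manifest."""
    return PipelineRun(config).run()


# -- selection-call serialisation -------------------------------------------

def _write_calls(calls, path) -> None:
    rows = []
    for c in calls:
        rows.append({
            "codon_index": c.codon_index, "lrt": c.lrt_stat, "p": c.p_value,
            "q": c.q_value, "lrt_pur": c.lrt_pur, "p_pur": c.p_pur,
            "q_pur": c.q_pur, "category": c.category,
            "omega_plus": c.omega_plus, "omega_minus": c.omega_minus,
            "p_minus": c.p_minus, "n_usable": c.n_usable,
            "n_substitutions": c.n_substitutions,
            "n_branches_selected": len(c.branches_selected),
            "branches_selected": ",".join(
                str(b) for b in sorted(c.branches_selected)),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.6g")


def _read_calls(path) -> list:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     na_values=["nan"])
    calls = []
    for _, r in df.iterrows():
        branches = frozenset(int(b) for b in str(r["branches_selected"]).split(",")
                             if b not in ("", "nan"))
        calls.append(sel.SiteSelectionCall(
            codon_index=int(r["codon_index"]), lrt_stat=float(r["lrt"]),
            p_value=float(r["p"]), q_value=float(r["q"]),
            lrt_pur=float(r["lrt_pur"]), p_pur=float(r["p_pur"]),
            q_pur=float(r["q_pur"]), category=str(r["category"]),
            omega_plus=float(r["omega_plus"]),
            omega_minus=float(r["omega_minus"]),
            p_minus=float(r["p_minus"]), n_usable=int(r["n_usable"]),
            n_substitutions=int(r["n_substitutions"]),
            branches_selected=branches))
    return calls
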