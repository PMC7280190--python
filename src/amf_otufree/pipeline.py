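"""End-to-end pipeline: refdb → preprocess → assign → table → stats.

One entry point chains the stages over plain-text interchange files (TSV,
FASTA, FASTQ), recording a run manifest with the tool version, a config
hash, input digests, per-stage record counts and every seed, so that a rerun
with identical config and inputs reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import abundance as ab
from . import preprocess as pp
from . import refdb as rd
from . import simulate as sim
from . import stats as st
from . import taxa_assign as ta

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


DEFAULTS = {
    "seed": 1,
    "preprocess": {"min_len": 200, "min_meanq": 25.0},
    "assign": {"min_cov": 80.0, "min_ident": 97.0, "chimera_check": True},
    "table": {"rarefaction_depth": 7000, "min_replicate_count": 10, "under_depth": "keep"},
    "stats": {"n_perm": 999, "kw_alpha": 0.05, "lda_cutoff": 1.0, "lda_boot": 30},
}


def validate_config(config: dict) -> dict:
    """Validate and fill a flat pipeline config; raises ConfigError early."""
    cfg = json.loads(json.dumps(config))  # deep copy, also rejects non-JSON values
    for section, defaults in DEFAULTS.items():
        if isinstance(defaults, dict):
            block = cfg.setdefault(section, {})
            if not isinstance(block, dict):
                raise ConfigError(f"section {section!r} must be a mapping")
            for key, value in defaults.items():
                block.setdefault(key, value)
        else:
            cfg.setdefault(section, defaults)
    a = cfg["assign"]
    for key in ("min_cov", "min_ident"):
        if not 0 <= a[key] <= 100:
            raise ConfigError(f"assign.{key} must be a percentage in [0, 100], got {a[key]}")
    if cfg["preprocess"]["min_len"] < 0:
        raise ConfigError("preprocess.min_len must be non-negative")
    if cfg["table"]["rarefaction_depth"] <= 0:
        raise ConfigError("table.rarefaction_depth must be >= 1")
    if cfg["table"]["under_depth"] not in ("keep", "error"):
        raise ConfigError("table.under_depth must be 'keep' or 'error'")
    if not isinstance(cfg["seed"], int):
        raise ConfigError("seed must be an integer")
    if "simulate" not in cfg:
        for key in ("reference_fasta", "reads_fastq", "mids", "metadata"):
            if key not in cfg:
                raise ConfigError(f"config needs {key!r} (or a 'simulate' block)")
        if "primers" not in cfg or not {"forward", "reverse"} <= set(cfg["primers"]):
            raise ConfigError("config needs primers.forward and primers.reverse")
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _read_mid_map(path: Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample"], df["mid"]))


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    manifest: dict = {
        "tool_version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()[:16],
        "seeds": {"global": seed},
        "stages": {},
        "inputs": {},
    }

    # stage 0 (optional): simulate inputs
    if "simulate" in cfg:
        s = cfg["simulate"]
        truth = sim.simulate_reference(
            n_taxa=s.get("n_taxa", 12),
            length=s.get("length", 700),
            divergence=s.get("divergence", 0.08),
            seed=seed,
            n_withheld=s.get("n_withheld", 3),
        )
        metadata = sim.vineyard_design(s.get("n_replicates", 5))
        comps = sim.study_compositions(truth, metadata, seed=seed)
        mid_map = sim.make_mid_map(list(metadata.index), seed=seed)
        reads, truth_table = sim.simulate_reads(
            truth,
            comps,
            reads_per_sample=s.get("reads_per_sample", 1000),
            mid_map=mid_map,
            error_rate=s.get("error_rate", 0.005),
            chimera_fraction=s.get("chimera_fraction", 0.05),
            junk_fraction=s.get("junk_fraction", 0.10),
            seed=seed + 1,
        )
        sim_dir = out / "sim"
        sim_dir.mkdir(exist_ok=True)
        sim.write_reference_fasta(truth, sim_dir / "reference.fasta")
        pp.write_fastq(reads, sim_dir / "reads.fastq")
        pd.DataFrame(mid_map.items(), columns=["sample", "mid"]).to_csv(
            sim_dir / "mids.tsv", sep="\t", index=False
        )
        metadata.to_csv(sim_dir / "metadata.tsv", sep="\t")
        truth_table.to_csv(sim_dir / "truth.tsv", sep="\t", index=False)
        cfg["reference_fasta"] = str(sim_dir / "reference.fasta")
        cfg["reads_fastq"] = str(sim_dir / "reads.fastq")
        cfg["mids"] = str(sim_dir / "mids.tsv")
        cfg["metadata"] = str(sim_dir / "metadata.tsv")
        cfg.setdefault("primers", None)
        manifest["stages"]["simulate"] = {"reads": len(reads), "taxa": len(truth.taxa)}

    for key in ("reference_fasta", "reads_fastq", "mids", "metadata"):
        path = Path(cfg[key])
        if not path.exists():
            raise ConfigError(f"input {key} not found: {path}")
        manifest["inputs"][key] = _digest(path)

    # stage 1: reference database
    report: dict = {}
    if cfg.get("primers"):
        primers = rd.PrimerPair(cfg["primers"]["forward"], cfg["primers"]["reverse"])
        refdb = rd.build_reference_db(cfg["reference_fasta"], primers, report=report)
    else:
        # simulated references are already primer-delimited fragments
        raw = rd.load_reference_fasta(cfg["reference_fasta"], report=report)
        refdb = rd.deduplicate(
            [rd.ReferenceRecord(acc, taxon, seq) for acc, taxon, seq in raw]
        )
        report["univocal"] = len(refdb)
    rd.write_reference_db(refdb, out / "refdb")
    manifest["stages"]["refdb"] = report

    # stage 2: preprocess
    reads_in = pp.read_fastq(cfg["reads_fastq"])
    mid_map = _read_mid_map(Path(cfg["mids"]))
    per_sample, qc_report = pp.run_preprocess(
        reads_in,
        mid_map,
        min_len=cfg["preprocess"]["min_len"],
        min_meanq=cfg["preprocess"]["min_meanq"],
    )
    pp.write_per_sample_fastq(per_sample, out / "samples")
    qc_report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    n_pass = int((qc_report["status"] == "pass").sum())
    manifest["stages"]["preprocess"] = {
        "input": len(reads_in),
        "pass": n_pass,
        "fail": int((qc_report["status"] == "fail").sum()),
        "unassigned": int((qc_report["status"] == pp.UNASSIGNED).sum()),
    }

    # stage 3: assignment
    assignments, groups = ta.assign_reads(
        per_sample,
        refdb,
        min_cov=cfg["assign"]["min_cov"],
        min_ident=cfg["assign"]["min_ident"],
        chimera_check=cfg["assign"]["chimera_check"],
    )
    with open(out / "assignments.tsv", "w") as fh:
        fh.write("read_id\tsample\tlabel_kind\tlabel\tcoverage\tidentity\tchimera\n")
        for a in assignments:
            kind = a.label.kind if a.label else "unclassified"
            name = a.label.name if a.label else ""
            cov = f"{a.best_hit.coverage:.2f}" if a.best_hit else ""
            ident = f"{a.best_hit.identity:.2f}" if a.best_hit else ""
            fh.write(
                f"{a.read_id}\t{a.sample_id}\t{kind}\t{name}\t{cov}\t{ident}\t"
                f"{int(a.chimera_flag)}\n"
            )
    ta.export_representatives(groups, out / "de_novo_representatives.fasta")
    n_known = sum(1 for a in assignments if a.label and a.label.kind == "known")
    n_denovo = sum(1 for a in assignments if a.label and a.label.kind == "de_novo")
    n_chim = sum(1 for a in assignments if a.chimera_flag)
    manifest["stages"]["assign"] = {
        "input": n_pass,
        "known": n_known,
        "de_novo": n_denovo,
        "chimera": n_chim,
        "noise": n_pass - n_known - n_denovo - n_chim,
        "de_novo_groups": len(groups),
    }

    # stage 4: abundance table
    metadata = pd.read_csv(cfg["metadata"], sep="\t", index_col=0)
    table = ab.build_table(assignments, metadata)
    ab.write_counts_tsv(table, out / "counts_raw.tsv")
    rarefied = ab.rarefy(
        table,
        depth=cfg["table"]["rarefaction_depth"],
        seed=seed,
        under_depth=cfg["table"]["under_depth"],
    )
    filtered = ab.filter_low_abundance(rarefied, cfg["table"]["min_replicate_count"])
    ab.write_counts_tsv(filtered, out / "counts.tsv")
    curves = {}
    for sample in table.samples:
        row = table.counts.loc[sample]
        total = int(row.sum())
        if total:
            grid = np.unique(np.linspace(1, total, 25).astype(int))
            curves[sample] = ab.rarefaction_curve(row, grid)
    pd.DataFrame(
        [(s, int(d), v) for s, cur in curves.items() for d, v in cur.items()],
        columns=["sample", "depth", "expected_richness"],
    ).to_csv(out / "rarefaction_curves.tsv", sep="\t", index=False)
    venn_cols = [c for c in ("soil", "time") if c in metadata.columns]
    if venn_cols:
        presence = ab.taxon_presence(filtered, venn_cols)
        if 2 <= len(presence) <= 4:
            regions = ab.venn_partition(presence)
            pd.DataFrame(
                [("&".join(k), v) for k, v in regions.items()],
                columns=["region", "n_taxa"],
            ).to_csv(out / "venn.tsv", sep="\t", index=False)
    manifest["stages"]["table"] = {
        "input": n_known + n_denovo,
        "samples": len(filtered.samples),
        "taxa_raw": len(table.taxa),
        "taxa_filtered": len(filtered.taxa),
    }

    # stage 5: statistics
    alpha = st.alpha_diversity_table(filtered)
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t", index_label="sample")
    stats_manifest: dict = {}
    factor_cols = [c for c in ("soil", "time") if c in metadata.columns]
    if factor_cols:
        groups_lab = filtered.group_labels(factor_cols)
        if groups_lab.nunique() >= 2 and groups_lab.value_counts().min() >= 2:
            stat, p = st.alpha_group_test(alpha["shannon"].to_numpy(), groups_lab.to_numpy())
            stats_manifest["alpha_shannon_kw"] = {"statistic": stat, "p": p}
    dm = st.bray_curtis_matrix(filtered)
    dm.to_frame().to_csv(out / "bray_curtis.tsv", sep="\t", index_label="sample")
    ord_res = st.pcoa(dm)
    ord_res.coordinates.to_csv(out / "pcoa.tsv", sep="\t", index_label="sample")
    for factor in factor_cols:
        labels = filtered.metadata[factor].to_numpy()
        if len(np.unique(labels)) < 2:
            continue
        res = st.permanova(dm, labels, n_perm=cfg["stats"]["n_perm"], seed=seed)
        stats_manifest[f"permanova_{factor}"] = {
            "F": res.f_statistic,
            "R2": res.r_squared,
            "p": res.p_value,
        }
        diff = st.per_taxon_wilcoxon(filtered, factor)
        pd.DataFrame(
            [(d.taxon, d.statistic, d.p_raw, d.p_adj, d.effect, d.enriched) for d in diff],
            columns=["taxon", "statistic", "p_raw", "p_adj", "log2_median_ratio", "enriched"],
        ).to_csv(out / f"wilcoxon_{factor}.tsv", sep="\t", index=False)
    if factor_cols:
        lefse = st.lda_effect_size(
            filtered,
            factor_cols,
            kw_alpha=cfg["stats"]["kw_alpha"],
            lda_cutoff=cfg["stats"]["lda_cutoff"],
            n_boot=cfg["stats"]["lda_boot"],
            seed=seed,
        )
        pd.DataFrame(
            [(d.taxon, d.statistic, d.p_raw, d.p_adj, d.effect, d.enriched) for d in lefse],
            columns=["taxon", "kw_statistic", "p_raw", "p_adj", "lda_score", "enriched"],
        ).to_csv(out / "lefse.tsv", sep="\t", index=False)
        stats_manifest["lefse_reported"] = len(lefse)
    manifest["stages"]["stats"] = stats_manifest

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
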