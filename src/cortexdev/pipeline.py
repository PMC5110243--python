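"""Composed pipeline over all analysis stages, with config echo and manifest.

Stages run in dependency order::

    simulate -> preprocess -> signatures -> classify -> network -> de
    (consensus, mitosis, edu run independently of the transcriptomic chain)

Each stage reads its inputs from, and writes its outputs to, one artifact
directory, so stages can be re-run individually. The effective
configuration is echoed beside the outputs and hashed into a manifest; a
failed stage leaves a ``FAILED`` marker naming the stage and the error.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import FetalReference, ZoneReference, celltype_assign, cycle_assign, zone_assign
from .consensus_mask import mask_consensus, read_alignment_fasta, write_alignment_fasta, write_masked_consensus
from .diffexpr import de_zscores, specificity_calls
from .edu_model import CellCycleParams, LabelingCurve, fit_cumulative_labeling
from .expression_io import CellMeta, filter_genes, read_matrix_tsv, write_matrix_tsv
from .lineage_network import build_network, mst_pseudotime
from .mitosis_timing import (
    cleavage_angle,
    compare_groups,
    orientation_range,
    orientation_tracks_from_csv,
    orientation_tracks_to_csv,
    phase_durations,
    tracks_from_csv,
    tracks_to_csv,
)
from .signatures import pc1_signatures, score_cells, select_informative_genes
from .synthetic_data import (
    SimConfig,
    gen_expression,
    gen_labeling_curve,
    gen_mitosis_tracks,
    gen_orientation_tracks,
    gen_toy_alignment,
    gen_zone_reference,
)

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "preprocess",
    "signatures",
    "classify",
    "network",
    "de",
    "consensus",
    "mitosis",
    "edu",
)

#: Cell-cycle parameters used by the simulate stage's labeling curves
#: (hours; growth fraction is a free choice since the plateau height is
#: not a printed quantity).
EDU_SIM_PARAMS = {
    "human": dict(tc=46.5, ts=17.5, gf=0.9),
    "chimpanzee": dict(tc=43.8, ts=12.8, gf=0.9),
}
EDU_TIME_GRID_H = (1.0, 2.0, 6.0, 24.0, 36.0, 48.0)

#: Mitotic phase means/sds (minutes) for the simulate stage; the human
#: prometaphase+metaphase program runs 5 minutes longer than chimpanzee.
MITOSIS_SIM_GROUPS = [
    (
        "human_organoid",
        dict(prophase=5.5, prometaphase=8.8, metaphase=11.0, anaphase=2.2, telophase=5.5),
        dict(prophase=2.0, prometaphase=2.0, metaphase=2.0, anaphase=1.0, telophase=2.0),
        60,
    ),
    (
        "chimp_organoid",
        dict(prophase=5.5, prometaphase=7.7, metaphase=7.1, anaphase=2.2, telophase=5.5),
        dict(prophase=2.0, prometaphase=2.0, metaphase=2.0, anaphase=1.0, telophase=2.0),
        60,
    ),
]


@dataclass
class PipelineConfig:
    """All pipeline tunables; defaults are the study's stated values."""

    stages: list[str] = field(default_factory=lambda: list(STAGES))
    seed: int = 0
    outdir: str = "cortexdev_out"
    n_top: int = 100
    score_threshold: float = 5.0
    tau: float = 0.4
    flank: int = 6
    k_type: float = 1.0
    k_species: float = 2.0
    cleavage_offset_min: float = 2.2
    plateau_tol: float = 0.02
    n_pcs: int = 6
    max_per_pc: int = 200
    p_cut: float = 1e-3
    n_perm: int = 999
    min_cells_expressed: int = 2
    sim: dict = field(default_factory=dict)  # SimConfig overrides

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _require(out: Path, *names: str) -> None:
    missing = [n for n in names if not (out / n).exists()]
    if missing:
        raise FileNotFoundError(
            f"missing pipeline inputs {missing} in {out}; run earlier stages first"
        )


def _stage_simulate(cfg: PipelineConfig, out: Path) -> list[str]:
    sim_cfg = SimConfig(seed=cfg.seed, **cfg.sim)
    matrix, meta, truth = gen_expression(sim_cfg)
    write_matrix_tsv(matrix, out / "matrix.tsv")
    meta.write_csv(out / "meta.csv")
    pd.concat(
        [truth.pseudotime, truth.true_type, truth.true_phase, truth.species], axis=1
    ).to_csv(out / "truth_cells.csv", index_label="cell_id")
    gene_rows = (
        [(g, "NSPC", 0.0) for g in truth.signature_genes["NSPC"]]
        + [(g, "neuron", 0.0) for g in truth.signature_genes["neuron"]]
        + [(g, "g2m", 0.0) for g in truth.g2m_genes]
        + [(g, "species_shift", e) for g, e in truth.species_shift_genes.items()]
    )
    pd.DataFrame(gene_rows, columns=["gene", "role", "log2_effect"]).to_csv(
        out / "truth_genes.csv", index=False
    )
    (out / "markers_nspc.txt").write_text(
        "\n".join(truth.signature_genes["NSPC"]) + "\n"
    )
    (out / "markers_g2m.txt").write_text("\n".join(truth.g2m_genes) + "\n")

    # an independent draw stands in for the labelled fetal reference
    ref_cfg = dataclasses.replace(sim_cfg, seed=sim_cfg.seed + 1)
    ref_matrix, _, ref_truth = gen_expression(ref_cfg)
    write_matrix_tsv(ref_matrix, out / "reference_matrix.tsv")
    ref_truth.true_type.rename("type").to_frame().to_csv(
        out / "reference_types.csv", index_label="cell_id"
    )
    gen_zone_reference(ref_truth, ref_matrix).write_tsv(out / "zone_reference.tsv")

    tracks = gen_mitosis_tracks(MITOSIS_SIM_GROUPS, seed=cfg.seed)
    tracks_to_csv(tracks, out / "mitosis_tracks.csv")
    otracks = []
    for gi, label in enumerate(("human_organoid", "chimp_organoid")):
        otracks += gen_orientation_tracks(
            n=34, base_angle=80.0, jitter_sd=5.0, seed=cfg.seed + gi, group=label
        )
    orientation_tracks_to_csv(otracks, out / "orientation_tracks.csv")

    for si, (species, p) in enumerate(EDU_SIM_PARAMS.items()):
        curve = gen_labeling_curve(
            CellCycleParams(**p),
            EDU_TIME_GRID_H,
            noise_sd=0.01,
            seed=cfg.seed + si,
            replicates=3,
        )
        curve.to_csv(out / f"edu_{species}.csv")

    aln, aln_truth = gen_toy_alignment(
        length=300,
        n_snps=8,
        indels=[(60, 2, "b"), (150, 3, "a"), (220, 1, "b")],
        seed=cfg.seed,
    )
    write_alignment_fasta(aln, out / "alignment.fasta")
    (out / "alignment_truth.json").write_text(json.dumps(aln_truth, indent=1))
    return [
        "matrix.tsv", "meta.csv", "truth_cells.csv", "truth_genes.csv",
        "markers_nspc.txt", "markers_g2m.txt", "reference_matrix.tsv",
        "reference_types.csv", "zone_reference.tsv", "mitosis_tracks.csv",
        "orientation_tracks.csv", "edu_human.csv", "edu_chimpanzee.csv",
        "alignment.fasta", "alignment_truth.json",
    ]


def _stage_preprocess(cfg: PipelineConfig, out: Path) -> list[str]:
    _require(out, "matrix.tsv", "reference_matrix.tsv")
    for name in ("matrix.tsv", "reference_matrix.tsv"):
        m = read_matrix_tsv(out / name)
        filtered = filter_genes(m, min_cells=cfg.min_cells_expressed)
        write_matrix_tsv(filtered, out / f"filtered_{name}")
    return ["filtered_matrix.tsv", "filtered_reference_matrix.tsv"]


def _read_markers(out: Path, name: str) -> list[str] | None:
    path = out / name
    if not path.exists():
        return None
    return [line for line in path.read_text().splitlines() if line.strip()]


def _stage_signatures(cfg: PipelineConfig, out: Path) -> list[str]:
    _require(out, "filtered_matrix.tsv", "filtered_reference_matrix.tsv")
    ref = read_matrix_tsv(out / "filtered_reference_matrix.tsv")
    n_top = min(cfg.n_top, ref.n_genes // 2)
    if n_top < cfg.n_top:
        logger.info("n_top clamped to %d for %d genes", n_top, ref.n_genes)
    sig = pc1_signatures(ref, n_top=n_top, orient_genes=_read_markers(out, "markers_nspc.txt"))
    sig.write_tsv(out / "signatures.tsv")
    main = read_matrix_tsv(out / "filtered_matrix.tsv")
    score_cells(main, sig, threshold=cfg.score_threshold).to_csv(out / "scores.csv")
    informative = select_informative_genes(
        ref,
        n_pcs=cfg.n_pcs,
        max_per_pc=cfg.max_per_pc,
        p_cut=cfg.p_cut,
        n_perm=cfg.n_perm,
        seed=cfg.seed,
    )
    (out / "informative_genes.txt").write_text("\n".join(informative) + "\n")
    return ["signatures.tsv", "scores.csv", "informative_genes.txt"]


def _stage_classify(cfg: PipelineConfig, out: Path) -> list[str]:
    _require(
        out,
        "filtered_matrix.tsv",
        "filtered_reference_matrix.tsv",
        "reference_types.csv",
        "zone_reference.tsv",
        "signatures.tsv",
        "meta.csv",
    )
    main = read_matrix_tsv(out / "filtered_matrix.tsv")
    ref_m = read_matrix_tsv(out / "filtered_reference_matrix.tsv")
    ref_types = pd.read_csv(out / "reference_types.csv", index_col="cell_id")["type"]
    fetal = FetalReference(ref_m, ref_types)
    zone_ref = ZoneReference.read_tsv(out / "zone_reference.tsv")
    sig_table = pd.read_csv(out / "signatures.tsv", sep="\t")

    zones = zone_assign(main, zone_ref)
    zones.to_csv(out / "zones.csv")
    types = celltype_assign(main, fetal, genes=list(sig_table["gene"]))
    g2m_genes = _read_markers(out, "markers_g2m.txt") or list(
        sig_table.loc[sig_table["signature"] == "NSPC", "gene"]
    )
    progenitors = types.index[types.isin(["AP", "BP"])]
    phases = pd.Series("unassigned", index=main.cell_ids, name="cycle_phase")
    if len(progenitors) >= 6:
        sub = read_matrix_tsv(out / "filtered_matrix.tsv")
        sub.values = sub.values.loc[progenitors]
        phases.update(cycle_assign(sub, g2m_genes))

    meta = CellMeta.read_csv(out / "meta.csv")
    t = meta.table.set_index("cell_id")
    t.loc[types.index, "assigned_type"] = types
    t.loc[zones.index, "zone"] = zones["zone"]
    t.loc[phases.index, "cycle_phase"] = phases
    CellMeta(t.reset_index()).write_csv(out / "meta_annotated.csv")
    return ["zones.csv", "meta_annotated.csv"]


def _stage_network(cfg: PipelineConfig, out: Path) -> list[str]:
    _require(out, "filtered_matrix.tsv", "informative_genes.txt")
    main = read_matrix_tsv(out / "filtered_matrix.tsv")
    genes = _read_markers(out, "informative_genes.txt")
    net = build_network(main, genes=genes, tau=cfg.tau)
    net.write_edge_list(out / "network_edges.tsv")
    mst_pseudotime(main, genes=genes).write_csv(out / "pseudotime.csv")
    return ["network_edges.tsv", "pseudotime.csv"]


def _stage_de(cfg: PipelineConfig, out: Path) -> list[str]:
    _require(out, "filtered_matrix.tsv", "meta_annotated.csv")
    main = read_matrix_tsv(out / "filtered_matrix.tsv")
    meta = pd.read_csv(out / "meta_annotated.csv").set_index("cell_id")

    def cells(species: str, ctype: str) -> list[str]:
        sel = (meta["species"] == species) & (meta["assigned_type"] == ctype)
        return [c for c in meta.index[sel] if c in main.cell_ids]

    z_type = de_zscores(
        cells("human", "AP"), cells("human", "N"), main, comparison="AP-vs-N(human)"
    )
    z_species = de_zscores(
        cells("human", "AP"),
        cells("chimpanzee", "AP"),
        main,
        comparison="human-vs-chimp(AP)",
    )
    z_type.write_tsv(out / "z_celltype.tsv")
    z_species.write_tsv(out / "z_species.tsv")
    calls = specificity_calls(
        z_type, z_species, k_type=cfg.k_type, k_species=cfg.k_species
    )
    df = calls.classes.rename("class").to_frame()
    df["z_celltype"] = z_type.z
    df["z_species"] = z_species.z
    df.to_csv(out / "de_calls.tsv", sep="\t", index_label="gene")
    (out / "de_thresholds.json").write_text(json.dumps(calls.thresholds, indent=1))
    return ["z_celltype.tsv", "z_species.tsv", "de_calls.tsv", "de_thresholds.json"]


def _stage_consensus(cfg: PipelineConfig, out: Path) -> list[str]:
    _require(out, "alignment.fasta")
    aln = read_alignment_fasta(out / "alignment.fasta")
    cons = mask_consensus(aln, flank=cfg.flank)
    write_masked_consensus(cons, out / "consensus.fasta", out / "mask.bed")
    return ["consensus.fasta", "mask.bed"]


def _stage_mitosis(cfg: PipelineConfig, out: Path) -> list[str]:
    _require(out, "mitosis_tracks.csv", "orientation_tracks.csv")
    tracks = tracks_from_csv(out / "mitosis_tracks.csv")
    rows = []
    for t in tracks:
        d = phase_durations(t).as_dict()
        rows.append({"cell_id": t.cell_id, "group": t.group, **d})
    dur = pd.DataFrame(rows)
    dur.to_csv(out / "phase_durations.csv", index=False)
    reports = {}
    for phase in ("prophase", "prometa_meta", "anaphase", "telophase", "total"):
        by_group = {g: s[phase].to_numpy() for g, s in dur.groupby("group")}
        reports[phase] = compare_groups(by_group, phase=phase).to_json_dict()
    (out / "mitosis_report.json").write_text(json.dumps(reports, indent=1))

    otracks = orientation_tracks_from_csv(out / "orientation_tracks.csv")
    orows = [
        {
            "cell_id": t.cell_id,
            "group": t.group,
            "orientation_range_deg": orientation_range(t),
            "cleavage_angle_deg": cleavage_angle(t, offset=cfg.cleavage_offset_min),
        }
        for t in otracks
    ]
    pd.DataFrame(orows).to_csv(out / "orientation_summary.csv", index=False)
    return ["phase_durations.csv", "mitosis_report.json", "orientation_summary.csv"]


def _stage_edu(cfg: PipelineConfig, out: Path) -> list[str]:
    curves = sorted(out.glob("edu_*.csv"))
    if not curves:
        raise FileNotFoundError(f"no edu_*.csv labeling curves in {out}")
    params = {}
    for path in curves:
        fit = fit_cumulative_labeling(
            LabelingCurve.from_csv(path), plateau_tol=cfg.plateau_tol
        )
        params[path.stem.removeprefix("edu_")] = {
            "Tc_h": fit.tc,
            "Ts_h": fit.ts,
            "GF": fit.gf,
            "slope_per_h": fit.slope,
            "intercept": fit.intercept,
            "r_squared": fit.r_squared,
            "plateau_onset_h": fit.plateau_onset,
        }
    (out / "edu_params.json").write_text(json.dumps(params, indent=1))
    return ["edu_params.json"]


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "signatures": _stage_signatures,
    "classify": _stage_classify,
    "network": _stage_network,
    "de": _stage_de,
    "consensus": _stage_consensus,
    "mitosis": _stage_mitosis,
    "edu": _stage_edu,
}


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the selected stages in dependency order; returns the artifact dir.

    The effective configuration is written beside the outputs; a manifest
    records every artifact and the config hash. A stage failure leaves a
    ``FAILED`` marker (stage name and error) and re-raises.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    manifest: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    selected = [s for s in STAGES if s in config.stages]
    for stage in selected:
        logger.info("running stage %s", stage)
        try:
            outputs = _STAGE_FNS[stage](config, out)
        except Exception as exc:
            (out / "FAILED").write_text(f"{stage}: {exc}\n")
            raise
        manifest["stages"][stage] = outputs
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    failed = out / "FAILED"
    if failed.exists():
        failed.unlink()
    return out
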