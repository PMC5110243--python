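"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the structures the analysis assumes, not the raw
data: an apical-progenitor (AP) to basal-progenitor (BP) to neuron (N)
expression continuum in two species with marker programs, G1/G2M cell-cycle
structure, Bernoulli dropout and a small set of species-shifted genes;
four-zone bulk reference profiles; group-structured mitotic event tracks
and spindle-angle tracks; and linear-accumulation labeling curves with a
plateau.

The expression model is additive on the log2(FPKM+1) scale: per-gene
baseline plus type, cycle and species programs, Gaussian noise, then hard
zeros for dropout and clipping at zero. Every generator takes one integer
seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ZoneReference
from .consensus_mask import PairwiseAlignment
from .edu_model import CellCycleParams, LabelingCurve, predict_labeling
from .expression_io import LOG2P1, CellMeta, ExpressionMatrix
from .mitosis_timing import EVENT_FIELDS, PHASE_NAMES, MitosisTrack, OrientationTrack


class InvalidConfig(ValueError):
    """A generator configuration violates its preconditions."""


@dataclass
class SimConfig:
    """Study conditions for :func:`gen_expression`.

    Effect sizes are in log2 units. Defaults describe the regime the
    recovery suites run under: 60 cells per species, 300 genes, 2.0-log2
    programs, noise sd 0.3 and no dropout. Dropout here is Bernoulli per
    entry and magnitude-independent, which makes even a few percent
    devastating to highly expressed markers; deeply sequenced full-length
    libraries have essentially no technical zeros among such genes, so the
    default is zero and the knob is exercised explicitly where wanted.
    """

    n_cells: int = 60  # per species
    n_genes: int = 300
    type_effect: float = 2.0
    cycle_effect: float = 2.0
    species_effect: float = 2.0
    dropout_rate: float = 0.0
    noise_sd: float = 0.3
    seed: int = 0
    base_mean: float = 4.0
    base_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_cells < 6 or self.n_genes < 20:
            raise InvalidConfig("need n_cells >= 6 per species and n_genes >= 20")
        if min(self.type_effect, self.cycle_effect, self.species_effect) < 0:
            raise InvalidConfig("effect sizes must be >= 0")
        if not (0 <= self.dropout_rate <= 1):
            raise InvalidConfig("dropout rate must be in [0, 1]")
        if self.noise_sd < 0:
            raise InvalidConfig("noise sd must be >= 0")


@dataclass
class SimTruth:
    """Ground truth attached to a synthetic expression matrix."""

    pseudotime: pd.Series  # cell -> [0, 1]
    true_type: pd.Series  # cell -> AP/BP/N
    true_phase: pd.Series  # cell -> G1/G2M
    species: pd.Series  # cell -> human/chimpanzee
    species_shift_genes: pd.Series  # gene -> signed log2 effect (+ = human up)
    signature_genes: dict[str, list[str]] = field(default_factory=dict)  # NSPC/neuron
    g2m_genes: list[str] = field(default_factory=list)
    bp_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        nspc = set(self.signature_genes.get("NSPC", []))
        neuron = set(self.signature_genes.get("neuron", []))
        if nspc & neuron:
            raise ValueError("signature gene sets overlap")


def _type_from_pseudotime(u: np.ndarray) -> np.ndarray:
    return np.where(u < 1 / 3, "AP", np.where(u < 2 / 3, "BP", "N"))


def gen_expression(
    config: SimConfig,
) -> tuple[ExpressionMatrix, CellMeta, SimTruth]:
    """Simulate a two-species AP->BP->N continuum with known truth.

    Marker programs occupy disjoint gene blocks (~8% of genes each for the
    NSPC, neuron, BP and cycle programs, ~4% for species-shifted genes),
    all on a common constitutive baseline: NSPC-signature genes ramp down
    along pseudotime and neuron-signature genes ramp up (PAX6-like vs
    NEUROD6-like); BP genes carry a mid-trajectory bump (TBR2-like), which
    makes the type signal more than one-dimensional so correlation-based
    classifiers can separate the intermediate state; G2M genes are raised
    in G2M-phase cells with per-gene weights (a uniform shift would be
    invisible to Pearson-correlation clustering); species-shifted genes
    carry the NSPC ramp plus a ``species_effect`` bonus in human AP cells,
    modelling progenitor genes whose AP expression moved between the
    species. Remaining genes are background with per-gene baselines.
    Progenitors are G2M with probability one half; neurons are postmitotic
    (G1).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_total = 2 * cfg.n_cells
    species = np.array(["human"] * cfg.n_cells + ["chimpanzee"] * cfg.n_cells)
    cell_ids = [
        f"human_{i:04d}" if sp == "human" else f"chimp_{i - cfg.n_cells:04d}"
        for i, sp in enumerate(species)
    ]
    gene_ids = [f"gene_{j:05d}" for j in range(cfg.n_genes)]

    u = rng.uniform(0, 1, n_total)
    true_type = _type_from_pseudotime(u)
    is_progenitor = true_type != "N"
    true_phase = np.where(
        is_progenitor & (rng.uniform(size=n_total) < 0.5), "G2M", "G1"
    )

    n_sig = max(4, round(0.08 * cfg.n_genes))
    n_shift = max(2, round(0.04 * cfg.n_genes))
    nspc_genes = gene_ids[:n_sig]
    neuron_genes = gene_ids[n_sig : 2 * n_sig]
    bp_genes = gene_ids[2 * n_sig : 3 * n_sig]
    g2m_genes = gene_ids[3 * n_sig : 4 * n_sig]
    shift_genes = gene_ids[4 * n_sig : 4 * n_sig + n_shift]
    n_program = 4 * n_sig + n_shift

    # type-marker genes share a constitutive baseline; cycle genes have
    # low, varied basal levels; background genes vary gene-to-gene
    base = rng.normal(cfg.base_mean, cfg.base_sd, cfg.n_genes).clip(min=0.5)
    program_base = cfg.base_mean + 0.5
    base[:n_program] = program_base
    base[3 * n_sig : 4 * n_sig] = rng.normal(
        cfg.base_mean - 2.0, 0.8, n_sig
    ).clip(min=0.2)
    x = np.tile(base, (n_total, 1))
    # tent-shaped marker programs along pseudotime: NSPC markers peak at
    # the AP end, BP markers mid-trajectory, neuron markers at the N end.
    # Each gene gets its own switch-off point / onset / width so that the
    # *direction* of the marker profile keeps changing along the whole
    # trajectory (a single shared ramp is scale-only within the terminal
    # segments, which Pearson-based ordering cannot resolve).
    uc = u[:, None]
    nspc_off = rng.uniform(0.5, 1.0, n_sig)  # switch-off pseudotime per gene
    neuron_on = rng.uniform(0.0, 0.5, n_sig)  # onset pseudotime per gene
    bp_width = rng.uniform(1 / 6, 1 / 3, n_sig)  # tent half-width per gene
    x[:, :n_sig] += np.maximum(0.0, 1.0 - uc / nspc_off) * cfg.type_effect
    x[:, n_sig : 2 * n_sig] += (
        np.maximum(0.0, (uc - neuron_on) / (1.0 - neuron_on)) * cfg.type_effect
    )
    x[:, 2 * n_sig : 3 * n_sig] += (
        np.maximum(0.0, 1.0 - np.abs(uc - 0.5) / bp_width) * cfg.type_effect
    )
    g2m_weights = rng.uniform(0.2, 1.8, n_sig)
    x[:, 3 * n_sig : 4 * n_sig] += np.outer(
        (true_phase == "G2M").astype(float), g2m_weights * cfg.cycle_effect
    )
    sl = slice(4 * n_sig, 4 * n_sig + n_shift)
    # progenitor ramp on the shifted genes (fixed switch-off at u = 2/3)
    x[:, sl] += np.maximum(0.0, 1.0 - 1.5 * uc) * cfg.type_effect
    human_ap = (species == "human") & (true_type == "AP")
    x[:, sl] += human_ap[:, None] * cfg.species_effect

    x += rng.normal(0, cfg.noise_sd, x.shape)
    drop = rng.uniform(size=x.shape) < cfg.dropout_rate
    x[drop] = 0.0
    x = x.clip(min=0.0)

    matrix = ExpressionMatrix(
        pd.DataFrame(x, index=cell_ids, columns=gene_ids), scale=LOG2P1
    )
    meta = CellMeta.from_columns(cell_ids, species, source="organoid")
    truth = SimTruth(
        pseudotime=pd.Series(u, index=cell_ids, name="pseudotime"),
        true_type=pd.Series(true_type, index=cell_ids, name="true_type"),
        true_phase=pd.Series(true_phase, index=cell_ids, name="true_phase"),
        species=pd.Series(species, index=cell_ids, name="species"),
        species_shift_genes=pd.Series(
            cfg.species_effect, index=shift_genes, name="log2_effect"
        ),
        signature_genes={"NSPC": list(nspc_genes), "neuron": list(neuron_genes)},
        g2m_genes=list(g2m_genes),
        bp_genes=list(bp_genes),
    )
    return matrix, meta, truth


def gen_zone_reference(truth: SimTruth, matrix: ExpressionMatrix) -> ZoneReference:
    """Four-zone bulk profiles as pseudotime-quartile means.

    VZ, iSVZ, oSVZ and CP profiles are the mean expression of cells whose
    pseudotime falls in the successive quartile intervals (closed at both
    ends, so degenerate pseudotime distributions place cells in every
    zone). Requires at least four cells.
    """
    ids = list(matrix.cell_ids)
    if set(ids) != set(truth.pseudotime.index):
        raise ValueError("truth and matrix cell ids disagree")
    if len(ids) < 4:
        raise InvalidConfig(f"need >= 4 cells for zone profiles, have {len(ids)}")
    u = truth.pseudotime[ids].to_numpy()
    edges = np.quantile(u, [0.0, 0.25, 0.5, 0.75, 1.0])
    profiles = {}
    for zone, lo, hi in zip(("VZ", "iSVZ", "oSVZ", "CP"), edges[:-1], edges[1:]):
        members = (u >= lo - 1e-12) & (u <= hi + 1e-12)
        profiles[zone] = matrix.values.loc[np.array(ids)[members]].mean(axis=0)
    return ZoneReference(pd.DataFrame(profiles))


def gen_mitosis_tracks(
    groups: Sequence[tuple[str, dict[str, float], dict[str, float], int]],
    frame_interval: float = 1.1,
    seed: int = 0,
) -> list[MitosisTrack]:
    """Simulate mitotic event tracks for labelled groups.

    ``groups`` is a sequence of (label, mean-per-phase, sd-per-phase, n)
    with phases ``prophase, prometaphase, metaphase, anaphase, telophase``
    in minutes. Phase durations are truncated-normal (truncated below at
    one frame), snapped to the frame grid with a one-frame minimum, and
    cumulated into event times starting at zero.
    """
    if frame_interval <= 0:
        raise InvalidConfig("frame interval must be positive")
    rng = np.random.default_rng(seed)
    tracks = []
    for label, means, sds, n in groups:
        for phase in PHASE_NAMES:
            if means[phase] <= 0:
                raise InvalidConfig(f"{label}: mean {phase} must be > 0")
            if sds[phase] < 0:
                raise InvalidConfig(f"{label}: sd {phase} must be >= 0")
        for i in range(n):
            durations = []
            for phase in PHASE_NAMES:
                mu, sd = means[phase], sds[phase]
                if sd == 0:
                    d = mu
                else:
                    a = (frame_interval - mu) / sd
                    d = stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, random_state=rng)
                d = max(frame_interval, round(d / frame_interval) * frame_interval)
                durations.append(d)
            times = np.concatenate([[0.0], np.cumsum(durations)])
            tracks.append(
                MitosisTrack(
                    cell_id=f"{label}_{i:04d}",
                    group=label,
                    frame_interval=frame_interval,
                    **dict(zip(EVENT_FIELDS, times)),
                )
            )
    return tracks


def gen_orientation_tracks(
    n: int,
    base_angle: float = 45.0,
    drift_per_min: float = 0.0,
    jitter_sd: float = 5.0,
    metaphase_min: float = 6.6,
    post_anaphase_min: float = 4.4,
    frame_interval: float = 1.1,
    seed: int = 0,
    group: str = "",
) -> list[OrientationTrack]:
    """Simulate chromosome-plate angle tracks.

    Each track samples the angle ``base_angle + drift_per_min * t +
    N(0, jitter_sd)`` (clipped to [0, 90]) on the frame grid from plate
    formation (t = 0) through ``post_anaphase_min`` past anaphase onset
    (t = ``metaphase_min``). ``post_anaphase_min`` must cover the 2.2-min
    cleavage-angle readout.
    """
    if not (0 <= base_angle <= 90):
        raise InvalidConfig("base angle must be in [0, 90]")
    if jitter_sd < 0 or frame_interval <= 0:
        raise InvalidConfig("jitter sd must be >= 0 and frame interval > 0")
    rng = np.random.default_rng(seed)
    t_plate, t_ana = 0.0, round(metaphase_min / frame_interval) * frame_interval
    times = np.arange(0.0, t_ana + post_anaphase_min + frame_interval / 2, frame_interval)
    tracks = []
    for i in range(n):
        angles = base_angle + drift_per_min * times
        if jitter_sd > 0:
            angles = angles + rng.normal(0, jitter_sd, times.shape)
        tracks.append(
            OrientationTrack(
                cell_id=f"{group or 'cell'}_{i:04d}",
                times=times.copy(),
                angles=np.clip(angles, 0.0, 90.0),
                t_plate_formed=t_plate,
                t_anaphase_onset=t_ana,
                group=group,
            )
        )
    return tracks


def gen_labeling_curve(
    params: CellCycleParams,
    times: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    replicates: int = 1,
) -> LabelingCurve:
    """Cumulative-labeling observations from the linear-rise/plateau model.

    The noiseless value at time t is min(GF*(t+Ts)/Tc, GF); Gaussian noise
    is added and the result clipped to [0, 1].
    """
    t = np.asarray(list(times), dtype=float)
    if (t < 0).any():
        raise InvalidConfig("times must be >= 0")
    if noise_sd < 0:
        raise InvalidConfig("noise sd must be >= 0")
    rng = np.random.default_rng(seed)
    t_all = np.repeat(t, replicates)
    rep = np.tile(np.arange(replicates), len(t))
    li = predict_labeling(params, t_all)
    if noise_sd > 0:
        li = li + rng.normal(0, noise_sd, li.shape)
    return LabelingCurve(t_all, np.clip(li, 0.0, 1.0), replicate=rep)


def gen_toy_alignment(
    length: int,
    n_snps: int = 0,
    indels: Sequence[tuple[int, int, str]] = (),
    seed: int = 0,
) -> tuple[PairwiseAlignment, dict]:
    """Random two-sequence alignment with configured SNPs and indels.

    ``indels`` are (reference position, length, which) where ``which`` is
    ``"a"`` (gap in the reference = insertion into seq_b, anchored at the
    reference position) or ``"b"`` (gap in seq_b = deletion, consuming
    reference bases). Events must not overlap; SNPs are placed uniformly on
    reference positions untouched by any indel. Returns the alignment and
    the ground-truth event lists.
    """
    if length < 1:
        raise InvalidConfig("length must be >= 1")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    blocked: set[int] = set()
    for pos, ln, which in indels:
        if which not in ("a", "b") or ln < 1:
            raise InvalidConfig(f"bad indel spec ({pos}, {ln}, {which!r})")
        span = range(pos, pos + ln) if which == "b" else range(pos, pos + 1)
        if which == "b" and pos + ln > length:
            raise InvalidConfig(f"indel at {pos} length {ln} exceeds bounds")
        if which == "a" and not (0 <= pos <= length):
            raise InvalidConfig(f"insertion point {pos} out of bounds")
        if blocked & set(span):
            raise InvalidConfig("overlapping indel events")
        blocked |= set(span)

    free = [p for p in range(length) if p not in blocked]
    if n_snps > len(free):
        raise InvalidConfig("more SNPs than available positions")
    snp_positions = sorted(rng.choice(free, size=n_snps, replace=False).tolist())

    ref = rng.choice(bases, size=length)
    cols_a: list[str] = []
    cols_b: list[str] = []
    del_at: dict[int, int] = {}
    ins_at: dict[int, int] = {}
    for pos, ln, which in indels:
        (del_at if which == "b" else ins_at)[pos] = ln
    snp_set = set(snp_positions)
    for p in range(length + 1):
        if p in ins_at:  # insertion into seq_b before reference position p
            ins = rng.choice(bases, size=ins_at[p])
            cols_a.extend("-" * ins_at[p])
            cols_b.extend(ins.tolist())
        if p == length:
            break
        a = ref[p]
        if any(start <= p < start + ln for start, ln in del_at.items()):
            cols_a.append(a)
            cols_b.append("-")
        elif p in snp_set:
            alt = rng.choice([b for b in "ACGT" if b != a])
            cols_a.append(a)
            cols_b.append(str(alt))
        else:
            cols_a.append(a)
            cols_b.append(a)
    aln = PairwiseAlignment("".join(cols_a), "".join(cols_b))
    truth = {"snp_positions": snp_positions, "indels": list(indels)}
    return aln, truth
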