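"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator emulates one input the analysis chain consumes — SELEX round
FASTQ pools with planted enrichment dynamics, saturation-binding
dose-response tables with known parameters, labelled tissue cohorts with
known contingencies, proteomic tables constructed to pass or fail each
shortlist filter, and coordinate trajectories with planted conformational
clusters and hydrogen-bond events — so every downstream operation can be
validated against a planted truth without any external data.

All generators are deterministic given their config (which carries the
seed); one global seed feeds independent per-generator substreams via
``numpy.random.SeedSequence.spawn`` keyed by generator name, so adding a
generator never perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binding import BindingModelParams, model_response
from .selex import QualityRead
from .shortlist import status_column
from .trajectory import HBondSpec, Trajectory

__all__ = [
    "SelexSimConfig",
    "BindingSimConfig",
    "CohortSimConfig",
    "TrajectorySimConfig",
    "gen_selex_rounds",
    "gen_binding_curve",
    "gen_recognition_cohort",
    "gen_proteomic_tables",
    "gen_trajectory",
]

_BASES = np.array(list("ACGT"))

# substream keys: stable per generator so streams are mutually independent
_STREAMS = {"selex": 0, "binding": 1, "cohort": 2, "proteome": 3, "trajectory": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    child = np.random.SeedSequence(seed).spawn(len(_STREAMS))[_STREAMS[stream]]
    return np.random.default_rng(child)


# ---------------------------------------------------------------------------
# SELEX rounds


@dataclass(frozen=True)
class SelexSimConfig:
    """Conditions of a simulated Cell-SELEX sequencing experiment.

    The defaults mirror a 12-round selection of a 76-nt library with a 30-nt
    random region between constant primer flanks; planted sequences are
    embedded at full library length so the minimum-length filter interacts
    realistically.  ``planted`` maps full-length sequences to their per-round
    enrichment factor (> 1 means the sequence's relative weight multiplies
    by that factor each round).
    """

    n_rounds: int = 12
    reads_per_round: int = 10_000
    library_length: int = 76
    random_region: int = 30
    planted: tuple[tuple[str, float], ...] = ()
    background_diversity: int = 10_000
    mean_quality: float = 36.0
    quality_sd: float = 3.0
    tail_degradation: float = 0.0  # Phred units lost per base over the 3' half
    flank5: str | None = None
    flank3: str | None = None
    round_labels: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rounds < 1 or self.reads_per_round < 0:
            raise ValueError("n_rounds must be >= 1 and reads_per_round >= 0")
        if self.library_length < 1 or self.background_diversity < 1:
            raise ValueError("library_length and background_diversity must be >= 1")
        for seq, factor in self.planted:
            if factor <= 0:
                raise ValueError(f"enrichment factor must be > 0, got {factor}")
            if len(seq) > self.library_length:
                raise ValueError(
                    f"planted sequence of length {len(seq)} exceeds library "
                    f"length {self.library_length}"
                )
        if self.round_labels is not None and len(self.round_labels) != self.n_rounds:
            raise ValueError("round_labels must have one label per round")

    @property
    def labels(self) -> tuple[str, ...]:
        if self.round_labels is not None:
            return self.round_labels
        return tuple(f"R{i + 1}" for i in range(self.n_rounds))


def _random_flanks(rng: np.random.Generator, config: SelexSimConfig) -> tuple[str, str]:
    constant = config.library_length - config.random_region
    n5 = constant // 2
    n3 = constant - n5
    flank5 = config.flank5 if config.flank5 is not None else "".join(rng.choice(_BASES, n5))
    flank3 = config.flank3 if config.flank3 is not None else "".join(rng.choice(_BASES, n3))
    return flank5, flank3


def gen_selex_rounds(
    config: SelexSimConfig,
) -> tuple[dict[str, list[QualityRead]], pd.DataFrame]:
    """Simulate per-round read pools with planted enrichment.

    Returns ``(rounds, truth)``: FASTQ-writable reads per round label, and a
    ground-truth table with one row per planted sequence and the realised
    count in every round.  Round ``r`` draws ``reads_per_round`` reads from a
    categorical distribution in which each background sequence keeps unit
    weight while planted sequence ``i`` has weight ``factor_i ** r``
    (relative to round 1), so a planted frequency is non-decreasing across
    rounds in expectation.
    """
    rng = _rng(config.seed, "selex")
    flank5, flank3 = _random_flanks(rng, config)
    n_rand = config.library_length - len(flank5) - len(flank3)
    background = set()
    while len(background) < config.background_diversity:
        need = config.background_diversity - len(background)
        chunk = rng.choice(_BASES, size=(need, n_rand))
        background.update(flank5 + "".join(row) + flank3 for row in chunk)
    background = sorted(background)
    planted_seqs = [s for s, _ in config.planted]
    factors = np.array([f for _, f in config.planted], dtype=float)
    pool = np.array(planted_seqs + background)

    rounds: dict[str, list[QualityRead]] = {}
    truth_counts = np.zeros((len(planted_seqs), config.n_rounds), dtype=int)
    for r, label in enumerate(config.labels):
        weights = np.concatenate(
            [factors**r if len(factors) else np.empty(0), np.ones(len(background))]
        )
        probs = weights / weights.sum()
        counts = rng.multinomial(config.reads_per_round, probs)
        reads: list[QualityRead] = []
        idx = 0
        for seq_i in np.nonzero(counts)[0]:
            seq = pool[seq_i]
            for _ in range(counts[seq_i]):
                quals = _simulate_qualities(rng, len(seq), config)
                reads.append(QualityRead(id=f"{label}_read{idx}", sequence=seq, qualities=quals))
                idx += 1
        order = rng.permutation(len(reads))
        rounds[label] = [reads[i] for i in order]
        truth_counts[:, r] = counts[: len(planted_seqs)]
    truth = pd.DataFrame(
        truth_counts, index=pd.Index(planted_seqs, name="sequence"), columns=list(config.labels)
    )
    truth.insert(0, "enrichment_factor", factors)
    return rounds, truth


def _simulate_qualities(
    rng: np.random.Generator, n: int, config: SelexSimConfig
) -> tuple[int, ...]:
    """Per-position Gaussian Phred truncated to [2, 41], with optional linear
    3' degradation over the second half of the read."""
    means = np.full(n, config.mean_quality, dtype=float)
    if config.tail_degradation > 0 and n > 1:
        half = n // 2
        ramp = np.arange(n - half, dtype=float)
        means[half:] -= config.tail_degradation * ramp
    q = rng.normal(means, config.quality_sd)
    return tuple(int(v) for v in np.clip(np.rint(q), 2, 41))


# ---------------------------------------------------------------------------
# Binding curves


@dataclass(frozen=True)
class BindingSimConfig:
    """Conditions of a simulated saturation-binding titration.

    Defaults use the customary five-dose titration (25–400 nM) with three
    independent replicates and additive Gaussian response noise.
    """

    true_params: BindingModelParams = field(
        default_factory=lambda: BindingModelParams(Bmax=100.0, Kd=150.0, NS=0.02, Background=5.0)
    )
    doses: tuple[float, ...] = (25.0, 50.0, 100.0, 200.0, 400.0)
    replicates: int = 3
    noise_sd: float = 0.0
    n_controls: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, float)
        if (d <= 0).any() or (np.diff(d) <= 0).any():
            raise ValueError("doses must be strictly positive and strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gen_binding_curve(config: BindingSimConfig) -> pd.DataFrame:
    """Simulate a tidy dose-response table from known parameters.

    Each replicate contributes one noisy response per dose plus
    ``n_controls`` zero-aptamer control rows (response = Background + noise).
    """
    rng = _rng(config.seed, "binding")
    p = config.true_params
    rows = []
    for rep in range(config.replicates):
        for dose in config.doses:
            resp = model_response(dose, p) + rng.normal(0.0, config.noise_sd) if config.noise_sd else model_response(dose, p)
            rows.append(
                {"dose_nM": dose, "response": float(resp), "replicate": rep, "control_type": ""}
            )
        for _ in range(config.n_controls):
            resp = p.Background + (rng.normal(0.0, config.noise_sd) if config.noise_sd else 0.0)
            rows.append(
                {"dose_nM": 0.0, "response": float(resp), "replicate": rep, "control_type": "no_aptamer"}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Recognition cohorts


@dataclass(frozen=True)
class CohortSimConfig:
    """Conditions of a simulated stained-tissue recognition cohort.

    The default cohort shape matches a 100-sample tissue microarray: 10
    adjacent non-tumoral tissues, 50 primary carcinomas and 40 lymph-node
    metastases.  Each aptamer stains tumor samples with its true-positive
    rate and adjacent samples with its false-positive rate; positive stains
    draw an ordinal intensity from ``intensity_distribution`` over
    {1: (+), 2: (++), 3: (+++)}.
    """

    n_adjacent: int = 10
    n_primary: int = 50
    n_metastatic: int = 40
    aptamers: tuple[str, ...] = ("AptaB1", "AptaB2", "AptaB3", "AptaB4", "AptaB5")
    true_positive_rate: float | Mapping[str, float] = 0.5
    false_positive_rate: float | Mapping[str, float] = 0.1
    subtype_proportions: tuple[tuple[str, float], ...] = (
        ("luminal", 0.56),
        ("HER2", 0.14),
        ("triple_negative", 0.20),
        ("unknown", 0.10),
    )
    intensity_distribution: tuple[float, float, float] = (0.25, 0.35, 0.40)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_adjacent, self.n_primary, self.n_metastatic) < 0:
            raise ValueError("stratum sizes must be nonnegative")
        props = np.array([p for _, p in self.subtype_proportions], float)
        if (props < 0).any() or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("subtype proportions must be >= 0 and sum to 1")
        dist = np.asarray(self.intensity_distribution, float)
        if (dist < 0).any() or abs(dist.sum() - 1.0) > 1e-9:
            raise ValueError("intensity distribution must be >= 0 and sum to 1")
        for rate in (*self._rates(self.true_positive_rate), *self._rates(self.false_positive_rate)):
            if not 0 <= rate <= 1:
                raise ValueError("rates must be in [0, 1]")

    def _rates(self, rate) -> list[float]:
        if isinstance(rate, Mapping):
            return [float(v) for v in rate.values()]
        return [float(rate)]

    def rate_for(self, aptamer: str, which: str) -> float:
        rate = self.true_positive_rate if which == "tpr" else self.false_positive_rate
        if isinstance(rate, Mapping):
            return float(rate[aptamer])
        return float(rate)


_STAGES = np.array(["I", "II", "III"])
_STAGE_P = np.array([0.09, 0.85, 0.06])
_GRADES = np.array(["I", "II", "III"])
_GRADE_P = np.array([0.17, 0.63, 0.20])
_TNM = np.array(
    ["T1N0M0", "T2N0M0", "T2N1M0", "T2N3M0", "T3N0M0", "T3N1M0", "T4N0M0", "T4N1M0"]
)
_TNM_P = np.array([0.08, 0.58, 0.12, 0.02, 0.08, 0.02, 0.06, 0.04])


def gen_recognition_cohort(
    config: CohortSimConfig,
) -> tuple[pd.DataFrame, dict[str, dict[str, int]]]:
    """Simulate a labelled cohort and record per-aptamer true contingencies.

    Returns ``(cohort, truth)`` where ``truth[aptamer]`` holds the planted
    TP/FP/FN/TN (tumor = primary + metastatic, positivity = any staining).
    """
    rng = _rng(config.seed, "cohort")
    classes = (
        ["adjacent"] * config.n_adjacent
        + ["primary_tumor"] * config.n_primary
        + ["metastatic"] * config.n_metastatic
    )
    n = len(classes)
    subtype_names = [s for s, _ in config.subtype_proportions]
    subtype_p = np.array([p for _, p in config.subtype_proportions])
    rows = []
    for i, cls in enumerate(classes):
        tumor = cls != "adjacent"
        rows.append(
            {
                "sample_id": f"S{i + 1:03d}",
                "class": cls,
                "subtype": rng.choice(subtype_names, p=subtype_p) if tumor else "unknown",
                "stage": rng.choice(_STAGES, p=_STAGE_P) if cls == "primary_tumor" else "unknown",
                "grade": rng.choice(_GRADES, p=_GRADE_P) if cls == "primary_tumor" else "unknown",
                "tnm": rng.choice(_TNM, p=_TNM_P) if cls == "primary_tumor" else "unknown",
            }
        )
    cohort = pd.DataFrame(rows)
    is_tumor = cohort["class"] != "adjacent"
    truth: dict[str, dict[str, int]] = {}
    levels = np.array([1, 2, 3])
    for apt in config.aptamers:
        tpr = config.rate_for(apt, "tpr")
        fpr = config.rate_for(apt, "fpr")
        stain_p = np.where(is_tumor, tpr, fpr)
        positive = rng.random(n) < stain_p
        intensity = np.zeros(n, dtype=int)
        npos = int(positive.sum())
        if npos:
            intensity[positive] = rng.choice(levels, size=npos, p=np.asarray(config.intensity_distribution))
        cohort[apt] = intensity
        truth[apt] = {
            "TP": int((positive & is_tumor).sum()),
            "FN": int((~positive & is_tumor).sum()),
            "FP": int((positive & ~is_tumor).sum()),
            "TN": int((~positive & ~is_tumor).sum()),
        }
    return cohort, truth


# ---------------------------------------------------------------------------
# Proteomic tables


@dataclass(frozen=True)
class ProteomeSimConfig:
    """Decoy composition for the shortlist-cascade fixture.

    The default composition reproduces the canonical cascade shape: with 4
    planted targets, 36 membrane decoys failing only the binding-phenotype
    filter and 249 non-membrane decoys failing only the membrane filter, the
    stage counts are 289 (fold change) -> 40 (membrane) -> 4 (phenotype).
    ``n_subthreshold_decoys`` adds proteins failing the fold-change filter
    itself.
    """

    recognized_lines: tuple[str, ...] = ("MDA-MB-468", "BT-474", "MCF-7")
    unrecognized_lines: tuple[str, ...] = ("HCC-1937",)
    n_membrane_decoys: int = 36
    n_nonmembrane_decoys: int = 249
    n_subthreshold_decoys: int = 0
    fold_factor: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_membrane_decoys, self.n_nonmembrane_decoys, self.n_subthreshold_decoys) < 0:
            raise ValueError("decoy counts must be nonnegative")
        if set(self.recognized_lines) & set(self.unrecognized_lines):
            raise ValueError("recognized and unrecognized line sets overlap")


def gen_proteomic_tables(
    planted_targets: Sequence[str], config: ProteomeSimConfig | None = None
) -> pd.DataFrame:
    """Construct a protein table on which the cascade recovers exactly
    ``planted_targets``.

    Planted targets pass every filter by construction; each decoy fails
    exactly one designated filter (phenotype, membrane, or fold change) and
    passes the others, so the per-stage survivor counts are fully determined
    by the composition.
    """
    config = config or ProteomeSimConfig()
    planted = list(planted_targets)
    if len(set(planted)) != len(planted):
        raise ValueError("duplicate protein ids in planted targets")
    rng = _rng(config.seed, "proteome")
    lines = (*config.recognized_lines, *config.unrecognized_lines)

    def abundances(pass_fold: bool) -> tuple[float, float]:
        control = float(rng.uniform(1.0, 10.0))
        f = config.fold_factor
        if pass_fold:
            # the pseudocount pc (<= this row's control) shifts the ratio
            # toward 1; target >= control * (2f - 1) keeps
            # (target + pc) / (control + pc) >= f for any pc in [0, control]
            target = control * float(rng.uniform(2 * f - 1 + 0.1, 4 * f))
        else:
            # a sub-f raw ratio only decreases under the pseudocount shift
            target = control * float(rng.uniform(0.2, 0.9 * f))
        return target, control

    def good_status() -> dict[str, str]:
        status = {status_column(l): "over" for l in config.recognized_lines}
        status.update({status_column(l): "under" for l in config.unrecognized_lines})
        return status

    def broken_status() -> dict[str, str]:
        status = good_status()
        line = lines[int(rng.integers(len(lines)))]
        wanted = status[status_column(line)]
        status[status_column(line)] = rng.choice(
            [s for s in ("over", "under", "unknown") if s != wanted]
        )
        return status

    rows = []
    for pid in planted:
        t, c = abundances(True)
        rows.append(
            {
                "protein_id": pid,
                "abundance_target": t,
                "abundance_control": c,
                "membrane_evidence": True,
                "predicted_localization": "plasma_membrane",
                **good_status(),
            }
        )
    for i in range(config.n_membrane_decoys):
        t, c = abundances(True)
        rows.append(
            {
                "protein_id": f"DECOY_MEM{i + 1:03d}",
                "abundance_target": t,
                "abundance_control": c,
                "membrane_evidence": True,
                "predicted_localization": "plasma_membrane",
                **broken_status(),
            }
        )
    for i in range(config.n_nonmembrane_decoys):
        t, c = abundances(True)
        # fail the membrane conjunction one way or the other
        evidence = bool(rng.random() < 0.5)
        rows.append(
            {
                "protein_id": f"DECOY_CYT{i + 1:03d}",
                "abundance_target": t,
                "abundance_control": c,
                "membrane_evidence": evidence,
                "predicted_localization": "other" if evidence else "plasma_membrane",
                **good_status(),
            }
        )
    for i in range(config.n_subthreshold_decoys):
        t, c = abundances(False)
        rows.append(
            {
                "protein_id": f"DECOY_LOW{i + 1:03d}",
                "abundance_target": t,
                "abundance_control": c,
                "membrane_evidence": True,
                "predicted_localization": "plasma_membrane",
                **good_status(),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "abundance_target",
            "abundance_control",
            "membrane_evidence",
            "predicted_localization",
            *[status_column(l) for l in lines],
        ],
    )
    if df["protein_id"].duplicated().any():
        raise ValueError("planted target ids collide with decoy ids")
    return df


# ---------------------------------------------------------------------------
# Trajectories


@dataclass(frozen=True)
class TrajectorySimConfig:
    """Conditions of a simulated multi-replicate trajectory.

    Frames are Gaussian-jittered copies of planted cluster centers; planted
    hydrogen bonds add a donor/hydrogen/acceptor atom triple whose geometry
    satisfies the default criterion in exactly the designated fraction of
    frames.  Three replicates mirror the usual repeat structure of
    production MD runs.
    """

    n_frames_per_replicate: int = 100
    n_replicates: int = 3
    n_atoms: int = 10
    n_centers: int = 2
    center_separation: float = 20.0
    jitter_sd: float = 0.1
    planted_hbonds: tuple[tuple[str, float], ...] = ()  # (name, occupancy fraction)
    cluster_cutoff: float = 2.5  # used only for the overlap warning
    frame_spacing_ns: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames_per_replicate < 1 or self.n_replicates < 1:
            raise ValueError("need at least one frame and one replicate")
        if self.n_atoms < 3:
            raise ValueError("need at least 3 atoms")
        if self.n_centers < 1:
            raise ValueError("need at least one cluster center")
        for name, occ in self.planted_hbonds:
            if not 0 <= occ <= 1:
                raise ValueError(f"hbond {name!r}: occupancy fraction must be in [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


@dataclass
class TrajectoryTruth:
    """Ground truth of a simulated trajectory."""

    cluster_of_frame: np.ndarray
    hbond_specs: list[HBondSpec]
    hbond_on_frames: dict[str, np.ndarray]
    clusters_may_overlap: bool


def gen_trajectory(config: TrajectorySimConfig) -> tuple[Trajectory, TrajectoryTruth]:
    """Simulate a trajectory with planted clusters and hydrogen-bond events.

    Cluster centers are independent Gaussian conformations whose pairwise
    superposed RMSD is of order ``center_separation``; when any realized
    pair falls within twice the clustering cutoff (or the jitter itself
    spans the cutoff) the truth carries an overlap warning flag.  Frames
    cycle through the centers in blocks within each replicate.  Each planted hbond appends three atoms: donor and
    hydrogen fixed near the structure, and an acceptor placed at ideal
    hydrogen-bonding geometry (2.9 A, collinear) in its designated frames and
    at 8 A otherwise; on-frames are an evenly spaced deterministic subset of
    size ``round(occupancy * n_frames)``.
    """
    from .trajectory import kabsch_superpose

    rng = _rng(config.seed, "trajectory")
    n_total = config.n_frames_per_replicate * config.n_replicates

    # independent Gaussian clouds are structurally distinct conformations:
    # with dispersion center_separation / 2 their pairwise *superposed* RMSD
    # is of order center_separation, well beyond the clustering cutoff
    centers = rng.normal(
        0.0, config.center_separation / 2.0, size=(config.n_centers, config.n_atoms, 3)
    )
    min_pair_rmsd = np.inf
    for i in range(config.n_centers):
        for j in range(i + 1, config.n_centers):
            min_pair_rmsd = min(min_pair_rmsd, kabsch_superpose(centers[i], centers[j])[2])

    # block assignment of frames to centers, repeated per replicate
    per_rep = np.repeat(
        np.arange(config.n_centers),
        int(np.ceil(config.n_frames_per_replicate / config.n_centers)),
    )[: config.n_frames_per_replicate]
    cluster_of_frame = np.tile(per_rep, config.n_replicates)

    coords = centers[cluster_of_frame] + rng.normal(
        0.0, config.jitter_sd, size=(n_total, config.n_atoms, 3)
    )
    labels = [f"CA:{i + 1}" for i in range(config.n_atoms)]

    specs: list[HBondSpec] = []
    on_frames: dict[str, np.ndarray] = {}
    anchor = 50.0  # keep hbond triples well away from the structural atoms
    for j, (name, occ) in enumerate(config.planted_hbonds):
        d = np.array([anchor + 10.0 * j, 0.0, 0.0])
        h = d + np.array([1.0, 0.0, 0.0])
        a_on = d + np.array([2.9, 0.0, 0.0])  # collinear D-H...A, 2.9 A
        a_off = d + np.array([8.0, 0.0, 0.0])
        n_on = int(round(occ * n_total))
        if n_on:
            step = n_total / n_on
            frames_on = np.unique((np.arange(n_on) * step).astype(int))[:n_on]
        else:
            frames_on = np.empty(0, dtype=int)
        triple = np.empty((n_total, 3, 3))
        triple[:, 0] = d
        triple[:, 1] = h
        triple[:, 2] = a_off
        triple[frames_on, 2] = a_on
        coords = np.concatenate([coords, triple], axis=1)
        dl, hl, al = (f"D{j + 1}:HB{j + 1}", f"H{j + 1}:HB{j + 1}", f"A{j + 1}:HB{j + 1}")
        labels += [dl, hl, al]
        specs.append(HBondSpec(donor=dl, hydrogen=hl, acceptor=al))
        on_frames[name] = frames_on

    boundaries = tuple(
        config.n_frames_per_replicate * i for i in range(1, config.n_replicates)
    )
    traj = Trajectory(
        coords=coords,
        labels=labels,
        replicate_boundaries=boundaries,
        frame_spacing_ns=config.frame_spacing_ns,
    )
    # expected per-frame deviation from its center is jitter_sd * sqrt(6)
    # (two jittered copies); flag when centers are not safely separated
    overlap = config.n_centers > 1 and (
        min_pair_rmsd <= 2 * config.cluster_cutoff
        or config.jitter_sd * np.sqrt(6.0) >= config.cluster_cutoff
    )
    truth = TrajectoryTruth(
        cluster_of_frame=cluster_of_frame,
        hbond_specs=specs,
        hbond_on_frames=on_frames,
        clusters_may_overlap=bool(overlap),
    )
    return traj, truth
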