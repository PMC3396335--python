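"""Synthetic two-group aCGH cohorts with known ground truth.

The generator emulates the study design the pipeline is built for: two
matched groups of tumors ("early" and "advanced" stage) sharing a single
landscape of candidate copy-number aberrations, with the advanced group
carrying every aberration at higher odds.  Each sample's probe-level
log2-ratio signal is

    state_amplitude x tumor_fraction  +  sinusoidal wave  +  N(0, noise_sd)

where the state amplitudes correspond to a single-copy loss, copy-neutral,
single-copy gain, and a high-level amplification, attenuated by the tumor
cell fraction of the specimen.  Survival times are exponential with a
group-dependent hazard and administrative censoring, so the advanced
group is both more aberrant and shorter-lived, as in the real cohort.

All randomness derives from one master seed through
``numpy.random.SeedSequence`` child streams, keyed by a draw counter, so
any partial rerun with the same config is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .clinical import ClinicalRecord, CohortTable
from .profiles import AcghProfileSet

TRUE_STATES = (-1, 0, 1, 2)  # loss, normal, gain, amplification


@dataclass
class SimConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the real cohort where it states a value: 16 samples
    per group, tumor fraction 0.778 (the cohort mean tumor percentage),
    and amplitudes of a single-copy loss/gain and a two-copy
    amplification in log2 units (-1, log2(3/2), log2(4/2)).
    """

    n_per_group: int = 16
    n_chromosomes: int = 8
    probes_per_chromosome: int = 150
    n_candidate_aberrations: int = 30
    p_aberration_early: float = 0.25
    odds_ratio_advanced: float = 3.0
    gain_amplitude: float = 0.585
    loss_amplitude: float = -1.0
    amp_amplitude: float = 1.0
    wave_amplitude: float = 0.10
    wave_period: float = 50.0        # probes; waves cycle a few times per chromosome
    noise_sd: float = 0.15
    tumor_fraction: float = 0.778
    hazard_ratio_highrisk: float = 3.0
    median_os_lowrisk: float = 120.0  # months; sets the baseline hazard
    censor_horizon: float = 150.0     # months, administrative censoring
    disjoint_aberrations: bool = False  # give each group its own candidate subset
    probe_spacing: int = 1_000_000    # bp between adjacent probes
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_aberration_early < 1.0):
            raise ValueError("p_aberration_early must be in [0, 1)")
        if self.odds_ratio_advanced <= 0:
            raise ValueError("odds_ratio_advanced must be > 0")
        if not (0.0 <= self.tumor_fraction <= 1.0):
            raise ValueError("tumor_fraction must be in [0, 1]")
        if self.probes_per_chromosome < 10:
            raise ValueError("probes_per_chromosome must be >= 10")
        for name in ("gain_amplitude", "loss_amplitude", "amp_amplitude",
                     "wave_amplitude", "noise_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.p_advanced() >= 1.0 - 1e-12:
            raise ValueError(
                "odds_ratio_advanced with p_aberration_early implies "
                "an advanced-group probability >= 1"
            )

    def p_advanced(self) -> float:
        """Per-aberration carrier probability in the advanced group."""
        p = self.p_aberration_early
        if p == 0.0:
            return 0.0
        odds = self.odds_ratio_advanced * p / (1.0 - p)
        return odds / (1.0 + odds)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulatedCohort:
    profiles: AcghProfileSet
    truth_states: np.ndarray                 # (n_probes, n_samples) in {-1,0,1,2}
    truth_segments: dict[str, list[tuple[int, int, int, int]]]
    clinical: CohortTable
    true_group: dict[str, str]               # sample -> early/advanced
    pairing: dict[str, str]                  # early sample <-> advanced sample
    config: SimConfig = field(repr=False, default=None)

    def truth_frame(self) -> pd.DataFrame:
        """Truth segments as a tidy table (1-based inclusive probe indices)."""
        rows = []
        for sample, segs in self.truth_segments.items():
            for chrom, start, end, state in segs:
                rows.append((sample, chrom, start, end, state))
        return pd.DataFrame(rows, columns=["sample", "chromosome", "start", "end", "state"])


def truth_call_matrix(cohort: "SimulatedCohort"):
    """Oracle call matrix straight from the simulated truth states.

    One-hot posteriors over (loss, normal, gain, amplification); hard
    calls with amplification folded into gain.  Lets downstream stages
    (regions, tests, clustering) be exercised at scale without paying
    for segmentation and calling.
    """
    from .calling import CallMatrix

    truth = cohort.truth_states
    n_probes, n_samples = truth.shape
    probs = np.zeros((n_probes, n_samples, 4))
    state_to_col = {-1: 0, 0: 1, 1: 2, 2: 3}
    for state, col in state_to_col.items():
        probs[..., col] = truth == state
    calls = truth.astype(np.int8).copy()
    calls[calls == 2] = 1
    return CallMatrix(
        probes=cohort.profiles.probes,
        samples=cohort.profiles.samples,
        calls=calls,
        probs=probs,
    )


_AMPLITUDE_KEYS = {-1: "loss_amplitude", 1: "gain_amplitude", 2: "amp_amplitude"}
_HISTOLOGY_P = {"C": 10 / 32, "E": 10 / 32, "M": 4 / 32, "S": 8 / 32}


def _child_rng(seed: int, counter: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(counter,)))


def _runs(states: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs of a vector as (start, end, value), 1-based inclusive."""
    change = np.flatnonzero(np.diff(states)) + 1
    bounds = np.concatenate(([0], change, [len(states)]))
    return [
        (int(bounds[k]) + 1, int(bounds[k + 1]), int(states[bounds[k]]))
        for k in range(len(bounds) - 1)
    ]


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Draw a synthetic cohort under ``config``; deterministic given the seed.

    A shared library of candidate aberration intervals (uniform length
    between 5 probes and half a chromosome) is drawn once; each early
    sample carries aberration k with probability p, each advanced sample
    with probability p' where odds(p') = odds_ratio x odds(p).  Later
    candidates overwrite earlier ones where they overlap, so per-sample
    truth states tile each chromosome.
    """
    cfg = config
    n_probes_total = cfg.n_chromosomes * cfg.probes_per_chromosome
    samples_early = [f"E{i+1:03d}" for i in range(cfg.n_per_group)]
    samples_adv = [f"A{i+1:03d}" for i in range(cfg.n_per_group)]
    samples = samples_early + samples_adv
    n_samples = len(samples)

    # probe grid: evenly spaced probes per chromosome
    chroms = np.repeat(np.arange(1, cfg.n_chromosomes + 1), cfg.probes_per_chromosome)
    pos = np.tile(
        (np.arange(cfg.probes_per_chromosome) + 1) * cfg.probe_spacing, cfg.n_chromosomes
    )
    probe_ids = [f"P{c:02d}_{i+1:04d}" for c, i in
                 zip(chroms, np.tile(np.arange(cfg.probes_per_chromosome), cfg.n_chromosomes))]
    probes = pd.DataFrame({"chromosome": chroms, "position": pos}, index=probe_ids)

    # candidate aberration library (shared landscape)
    rng_lib = _child_rng(cfg.seed, 0)
    max_len = max(5, cfg.probes_per_chromosome // 2)
    cand = []
    for _ in range(cfg.n_candidate_aberrations):
        chrom = int(rng_lib.integers(1, cfg.n_chromosomes + 1))
        length = int(rng_lib.integers(5, max_len + 1))
        start = int(rng_lib.integers(1, cfg.probes_per_chromosome - length + 2))
        state = int(rng_lib.choice([-1, 1, 2], p=[0.4, 0.45, 0.15]))
        cand.append((chrom, start, start + length - 1, state))

    # carrier draws
    p_early, p_adv = cfg.p_aberration_early, cfg.p_advanced()
    rng_car = _child_rng(cfg.seed, 1)
    carrier = np.zeros((cfg.n_candidate_aberrations, n_samples), dtype=bool)
    for k in range(cfg.n_candidate_aberrations):
        carrier[k, :cfg.n_per_group] = rng_car.random(cfg.n_per_group) < p_early
        carrier[k, cfg.n_per_group:] = rng_car.random(cfg.n_per_group) < p_adv
    if cfg.disjoint_aberrations:
        half = cfg.n_candidate_aberrations // 2
        carrier[:half, cfg.n_per_group:] = False   # first half: early only
        carrier[half:, :cfg.n_per_group] = False   # second half: advanced only

    # per-sample truth states; later candidates overwrite earlier ones
    truth = np.zeros((n_probes_total, n_samples), dtype=np.int8)
    offsets = {c: (c - 1) * cfg.probes_per_chromosome for c in range(1, cfg.n_chromosomes + 1)}
    for k, (chrom, start, end, state) in enumerate(cand):
        lo = offsets[chrom] + start - 1
        hi = offsets[chrom] + end
        truth[lo:hi, carrier[k]] = state

    # signal = amplitude(state) * tumor_fraction + wave + noise
    amp = np.zeros_like(truth, dtype=float)
    for state, key in _AMPLITUDE_KEYS.items():
        amp[truth == state] = getattr(cfg, key)
    signal = amp * cfg.tumor_fraction
    if cfg.wave_amplitude != 0.0:
        rng_wave = _child_rng(cfg.seed, 2)
        within = np.tile(np.arange(cfg.probes_per_chromosome), cfg.n_chromosomes)
        phases = rng_wave.uniform(0, 2 * np.pi, size=n_samples)
        wave = cfg.wave_amplitude * np.sin(
            2 * np.pi * within[:, None] / cfg.wave_period + phases[None, :]
        )
        signal = signal + wave
    if cfg.noise_sd > 0:
        rng_noise = _child_rng(cfg.seed, 3)
        signal = signal + rng_noise.normal(0.0, cfg.noise_sd, size=signal.shape)

    values = pd.DataFrame(signal, index=probe_ids, columns=samples)
    stage_labels = {s: "early" for s in samples_early}
    stage_labels.update({s: "advanced" for s in samples_adv})
    profiles = AcghProfileSet(probes, values, stage_labels)
    # construction sorts probes; our grid is already sorted, assert alignment
    assert list(profiles.values.columns) == samples

    truth_segments: dict[str, list[tuple[int, int, int, int]]] = {}
    for j, sample in enumerate(samples):
        segs = []
        for c in range(1, cfg.n_chromosomes + 1):
            vec = truth[offsets[c]:offsets[c] + cfg.probes_per_chromosome, j]
            segs.extend((c, s, e, v) for s, e, v in _runs(vec))
        truth_segments[sample] = segs

    clinical = _simulate_clinical(cfg, samples_early, samples_adv)
    true_group = dict(stage_labels)
    pairing = {e: a for e, a in zip(samples_early, samples_adv)}
    return SimulatedCohort(
        profiles=profiles,
        truth_states=truth,
        truth_segments=truth_segments,
        clinical=clinical,
        true_group=true_group,
        pairing=pairing,
        config=cfg,
    )


def _simulate_clinical(cfg: SimConfig, early: list[str], adv: list[str]) -> CohortTable:
    """Exponential survival with group-dependent hazard, censored at the horizon.

    The hazard is coupled to the true group only (advanced = high risk),
    keeping survival ground truth independent of the simulated calls.
    Ages and histology/grade follow the real cohort's marginals; each
    matched pair shares histology and grade, as in the study design.
    """
    rng = _child_rng(cfg.seed, 4)
    lam_early = np.log(2.0) / cfg.median_os_lowrisk
    lam_adv = lam_early * cfg.hazard_ratio_highrisk
    records = []
    hist_names = list(_HISTOLOGY_P)
    hist_p = np.array([_HISTOLOGY_P[h] for h in hist_names])
    for i, (se, sa) in enumerate(zip(early, adv)):
        hist = str(rng.choice(hist_names, p=hist_p))
        grade = int(rng.integers(1, 4))
        for sample, group, lam, figo in (
            (se, "early", lam_early, "I"),
            (sa, "advanced", lam_adv, "III"),
        ):
            mean_age = 52.0 if group == "early" else 62.0
            age = int(np.clip(round(rng.normal(mean_age, 10.0)), 27, 80))
            t = float(rng.exponential(1.0 / lam))
            dead = t < cfg.censor_horizon
            os_m = round(min(t, cfg.censor_horizon), 1)
            records.append(ClinicalRecord(
                sample_id=sample,
                age=age,
                stage_group=group,
                figo_stage=figo,
                histology=hist,
                grade=grade,
                chemo=group == "advanced",
                staging_quality="optimal",
                status="dead" if dead else "alive",
                os_months=os_m,
                progression=dead,
                pfs_months=os_m,
                cluster="unassigned",
            ))
    return CohortTable(records)
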