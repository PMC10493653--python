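"""End-to-end cohort simulation and study-shaped analysis.

Simulates a three-group cohort (migraineurs with a patent foramen ovale,
migraineurs without one, healthy controls) in which each subject's
ABP->CBFV relation is a first-order-lead system with a known phase target
at the analysis-band centre, and each subject carries an NN-interval
series with known band structure plus an injectable ectopic rate. The
study runner then performs per-subject transfer-function and HRV analysis,
applies the >20%-ectopic exclusion rule (HRV only: excluded subjects keep
their autoregulation results, so the two tables can have different ns),
and assembles group tables with one-way ANOVA / chi-square statistics.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import hrv as hrvmod
from . import stats as statsmod
from . import tfa as tfamod
from .hrv import HRVConfig
from .signals import UniformSignal, read_nn, read_pair, write_nn, write_pair
from .synth import (ABPSpec, AutoregFilterSpec, NNSpec, apply_autoreg_filter,
                    generate_abp, generate_nn_series, inject_ectopics)
from .tfa import TFAConfig

log = logging.getLogger(__name__)

_MAX_SEED = 2 ** 31 - 1


@dataclass(frozen=True)
class GroupSpec:
    """Generative parameters for one cohort group."""

    label: str
    n: int
    phase_mean_deg: float = 54.0     # autoregulation phase target at band centre
    phase_sd_deg: float = 5.0        # between-subject SD of the target
    hemisphere_jitter_deg: float = 2.0
    dc_gain: float = 0.65            # cm/s per mmHg at DC (CBFV ~60 at ABP ~90)
    cbfv_noise_sd: float = 0.6       # cm/s; sets in-band coherence near 0.75
    nn_mean_ms: float = 850.0
    nn_between_sd_ms: float = 80.0
    lf_amp_ms: float = 20.0
    hf_amp_ms: float = 22.0
    nn_noise_sd_ms: float = 5.0
    baseline_ectopic_fraction: float = 0.02
    n_high_ectopic: int = 0          # subjects given high_ectopic_fraction
    high_ectopic_fraction: float = 0.25
    age_mean: float = 37.0
    age_sd: float = 12.0
    male_fraction: float = 0.30
    comorbidity_rates: dict = field(default_factory=lambda: {
        "hypertension": 0.14, "hyperlipidemia": 0.20,
        "diabetes": 0.09, "smoking": 0.23})
    repeated_timepoints: bool = False  # simulate post / 1-month NN recordings

    def validate(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: n must be >= 2")
        if self.phase_sd_deg < 0:
            raise ValueError(f"group {self.label!r}: phase SD must be >= 0")
        if not 0 < self.phase_mean_deg < 90:
            raise ValueError(f"group {self.label!r}: phase mean must be in (0, 90)")
        if self.n_high_ectopic > self.n:
            raise ValueError(f"group {self.label!r}: n_high_ectopic exceeds n")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple
    duration_s: float = 600.0
    fs: float = 10.0
    n_beats: int = 700
    band_centre_hz: float = 0.09
    seed: int = 0

    def validate(self) -> None:
        if len(self.groups) < 1:
            raise ValueError("cohort needs at least one group")
        for g in self.groups:
            g.validate()


def default_cohort_spec(seed: int = 0, scale: float = 1.0) -> CohortSpec:
    """The study-shaped default: 45 / 50 / 50 subjects with phase targets
    (46, 54, 54) degrees, two high-ectopic subjects in the shunt group and
    one in each comparison group; ``scale`` shrinks group sizes for smoke
    runs."""
    def sz(n: int) -> int:
        return max(2, int(round(n * scale)))
    groups = (
        GroupSpec(label="pfo_migraine", n=sz(45), phase_mean_deg=46.0,
                  n_high_ectopic=min(2, sz(45)), repeated_timepoints=True),
        GroupSpec(label="migraine", n=sz(50), phase_mean_deg=54.0,
                  n_high_ectopic=min(1, sz(50))),
        GroupSpec(label="control", n=sz(50), phase_mean_deg=54.0,
                  n_high_ectopic=min(1, sz(50))),
    )
    return CohortSpec(groups=groups, seed=seed)


@dataclass
class Subject:
    subject_id: str
    group: str
    age: float
    male: bool
    comorbidities: dict
    abp: UniformSignal
    cbfv_left: UniformSignal
    cbfv_right: UniformSignal
    nn_raw: np.ndarray                     # intervals with ectopics injected
    true_phase_left_deg: float
    true_phase_right_deg: float
    injected_ectopic_fraction: float
    nn_repeated: Optional[list] = None     # [post, 1-month] raw interval arrays


@dataclass
class Cohort:
    spec: CohortSpec
    subjects: list

    @property
    def manifest(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            rows.append(dict(
                subject_id=s.subject_id, group=s.group,
                age=round(s.age, 1), male=int(s.male),
                **{k: int(v) for k, v in s.comorbidities.items()},
                true_phase_left_deg=round(s.true_phase_left_deg, 3),
                true_phase_right_deg=round(s.true_phase_right_deg, 3),
                injected_ectopic_fraction=round(s.injected_ectopic_fraction, 4),
                has_repeated=int(s.nn_repeated is not None),
            ))
        return pd.DataFrame(rows)


def _truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo < v < hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def _simulate_subject(sid: str, g: GroupSpec, spec: CohortSpec,
                      rng: np.random.Generator, high_ectopic: bool) -> Subject:
    seeds = rng.integers(0, _MAX_SEED, size=8)
    abp = generate_abp(ABPSpec(duration_s=spec.duration_s, fs=spec.fs,
                               seed=int(seeds[0])))
    subject_phase = _truncated_normal(rng, g.phase_mean_deg, g.phase_sd_deg,
                                      5.0, 85.0)
    phases = {}
    cbfv = {}
    for side, seed in (("left", seeds[1]), ("right", seeds[2])):
        ph = _truncated_normal(rng, subject_phase, g.hemisphere_jitter_deg,
                               5.0, 85.0)
        filt = AutoregFilterSpec.lead_for_phase(
            ph, spec.band_centre_hz, dc_gain=g.dc_gain,
            noise_sd=g.cbfv_noise_sd, noise_seed=int(seed))
        phases[side] = ph
        cbfv[side] = apply_autoreg_filter(abp, filt)

    def nn_spec(seed, mean_scale=1.0, amp_scale=1.0) -> NNSpec:
        return NNSpec(
            n_beats=spec.n_beats,
            mean_nn_ms=_truncated_normal(rng, g.nn_mean_ms * mean_scale,
                                         g.nn_between_sd_ms, 500.0, 1300.0),
            lf_amp_ms=g.lf_amp_ms * amp_scale * rng.uniform(0.8, 1.2),
            hf_amp_ms=g.hf_amp_ms * amp_scale * rng.uniform(0.8, 1.2),
            noise_sd_ms=g.nn_noise_sd_ms, seed=int(seed))

    frac = g.high_ectopic_fraction if high_ectopic else g.baseline_ectopic_fraction
    nn = inject_ectopics(generate_nn_series(nn_spec(seeds[3])), frac,
                         seed=int(seeds[4]))
    repeated = None
    if g.repeated_timepoints:
        # transient post-procedure dip in heart-period variability,
        # recovered by the 1-month visit
        post = inject_ectopics(generate_nn_series(
            nn_spec(seeds[5], mean_scale=0.95, amp_scale=0.6)),
            g.baseline_ectopic_fraction, seed=int(seeds[6]))
        month = inject_ectopics(generate_nn_series(nn_spec(seeds[7])),
                                g.baseline_ectopic_fraction, seed=int(seeds[6]))
        repeated = [post.intervals_ms, month.intervals_ms]

    return Subject(
        subject_id=sid, group=g.label,
        age=_truncated_normal(rng, g.age_mean, g.age_sd, 18.0, 65.0),
        male=bool(rng.random() < g.male_fraction),
        comorbidities={k: bool(rng.random() < p)
                       for k, p in g.comorbidity_rates.items()},
        abp=abp, cbfv_left=cbfv["left"], cbfv_right=cbfv["right"],
        nn_raw=nn.intervals_ms,
        true_phase_left_deg=phases["left"],
        true_phase_right_deg=phases["right"],
        injected_ectopic_fraction=frac,
        nn_repeated=repeated,
    )


def simulate_cohort(spec: CohortSpec, out_dir=None) -> Cohort:
    """Simulate a cohort; optionally write per-subject files and a manifest.

    Deterministic for a fixed ``spec.seed``. With ``out_dir`` set, each
    subject gets two paired-signal files (left/right hemisphere) and an
    NN file; the manifest CSV records group labels, demographics and the
    generative ground truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    subjects = []
    for g in spec.groups:
        for i in range(g.n):
            sid = f"{g.label}_{i + 1:03d}"
            subjects.append(_simulate_subject(sid, g, spec, rng,
                                              high_ectopic=i < g.n_high_ectopic))
    cohort = Cohort(spec=spec, subjects=subjects)
    log.info("simulated %d subjects in %d groups",
             len(subjects), len(spec.groups))
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _write_cohort(cohort: Cohort, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for s in cohort.subjects:
        write_pair(out / f"{s.subject_id}_left.csv", s.abp, s.cbfv_left)
        write_pair(out / f"{s.subject_id}_right.csv", s.abp, s.cbfv_right)
        write_nn(out / f"{s.subject_id}_nn.txt", s.nn_raw)
        if s.nn_repeated is not None:
            write_nn(out / f"{s.subject_id}_nn_post.txt", s.nn_repeated[0])
            write_nn(out / f"{s.subject_id}_nn_month.txt", s.nn_repeated[1])
    cohort.manifest.to_csv(out / "manifest.csv", index=False)


def load_cohort(in_dir) -> Cohort:
    """Reload a written cohort from its manifest and per-subject files."""
    d = Path(in_dir)
    manifest = pd.read_csv(d / "manifest.csv")
    subjects = []
    missing = []
    for _, r in manifest.iterrows():
        sid = r["subject_id"]
        paths = [d / f"{sid}_left.csv", d / f"{sid}_right.csv",
                 d / f"{sid}_nn.txt"]
        if r.get("has_repeated", 0):
            paths += [d / f"{sid}_nn_post.txt", d / f"{sid}_nn_month.txt"]
        if not all(p.exists() for p in paths):
            missing.append(sid)
            continue
        abp, cbfv_l = read_pair(paths[0])
        _, cbfv_r = read_pair(paths[1])
        repeated = None
        if r.get("has_repeated", 0):
            repeated = [read_nn(paths[3]), read_nn(paths[4])]
        subjects.append(Subject(
            subject_id=sid, group=r["group"], age=float(r["age"]),
            male=bool(r["male"]),
            comorbidities={k: bool(r[k]) for k in
                           ("hypertension", "hyperlipidemia",
                            "diabetes", "smoking")},
            abp=abp, cbfv_left=cbfv_l, cbfv_right=cbfv_r,
            nn_raw=read_nn(paths[2]),
            true_phase_left_deg=float(r["true_phase_left_deg"]),
            true_phase_right_deg=float(r["true_phase_right_deg"]),
            injected_ectopic_fraction=float(r["injected_ectopic_fraction"]),
            nn_repeated=repeated,
        ))
    if missing:
        raise FileNotFoundError(
            f"manifest lists subjects with missing files: {missing}")
    return Cohort(spec=None, subjects=subjects)


@dataclass
class StudyTables:
    """Study-shaped outputs: per-subject results plus group statistics."""

    demographics: pd.DataFrame
    tfa_subjects: pd.DataFrame
    tfa_groups: pd.DataFrame
    hrv_subjects: pd.DataFrame
    hrv_groups: pd.DataFrame
    repeated: pd.DataFrame
    exclusions: dict


def _group_anova_rows(df: pd.DataFrame, variables, group_col="group"):
    rows = []
    labels = list(dict.fromkeys(df[group_col]))
    for var in variables:
        samples = [df.loc[df[group_col] == lab, var].dropna().to_numpy()
                   for lab in labels]
        if any(len(s) < 2 for s in samples):
            continue
        res = statsmod.anova_raw(samples)
        row = dict(variable=var, method=res.method,
                   statistic=res.statistic, df1=res.df[0], df2=res.df[1],
                   p=res.p)
        for lab, s in zip(labels, samples):
            row[f"{lab}_n"] = len(s)
            row[f"{lab}_mean"] = float(np.mean(s))
            row[f"{lab}_sd"] = float(np.std(s, ddof=1))
        rows.append(row)
    return pd.DataFrame(rows)


def run_study(cohort: Cohort, tfa_cfg: TFAConfig = TFAConfig(),
              hrv_cfg: HRVConfig = HRVConfig()) -> StudyTables:
    """Per-subject TFA + HRV, exclusion bookkeeping, and group tables."""
    tfa_rows, hrv_rows, repeated_rows = [], [], []
    excluded_by_group: dict = {}
    for s in cohort.subjects:
        left = tfamod.analyze_pair(s.abp, s.cbfv_left, tfa_cfg)
        right = tfamod.analyze_pair(s.abp, s.cbfv_right, tfa_cfg)
        overall = tfamod.combine_hemispheres(left, right)
        tfa_rows.append(dict(
            subject_id=s.subject_id, group=s.group,
            phase_left=left.phase_deg, phase_right=right.phase_deg,
            phase_overall=overall.phase_deg,
            gain_left=left.gain, gain_right=right.gain,
            gain_overall=overall.gain,
            coherence_overall=overall.mean_coherence,
            valid=overall.valid,
            true_phase_left=s.true_phase_left_deg,
            true_phase_right=s.true_phase_right_deg,
        ))
        nn = hrvmod.clean_nn(s.nn_raw, hrv_cfg)
        row = dict(subject_id=s.subject_id, group=s.group,
                   ectopic_fraction=nn.ectopic_fraction, excluded=nn.excluded)
        if nn.excluded:
            excluded_by_group[s.group] = excluded_by_group.get(s.group, 0) + 1
            log.info("subject %s excluded from HRV (ectopic fraction %.1f%%)",
                     s.subject_id, 100 * nn.ectopic_fraction)
        else:
            td = hrvmod.time_domain(nn)
            fd = hrvmod.freq_domain(nn, hrv_cfg)
            row.update(mean_nn=td.mean_nn_ms, sdnn=td.sdnn_ms,
                       rmssd=td.rmssd_ms, log_sdnn=td.log_sdnn,
                       log_rmssd=td.log_rmssd, tp=fd.tp_ms2, vlf=fd.vlf_ms2,
                       lf=fd.lf_ms2, hf=fd.hf_ms2, log_tp=fd.log_tp,
                       log_vlf=fd.log_vlf, log_lf=fd.log_lf, log_hf=fd.log_hf,
                       nlf=fd.nlf, nhf=fd.nhf, lf_hf=fd.lf_hf_ratio)
            if s.nn_repeated is not None:
                tps = [td.log_sdnn]
                ok = True
                for raw in s.nn_repeated:
                    nn_t = hrvmod.clean_nn(raw, hrv_cfg)
                    if nn_t.excluded:
                        ok = False
                        break
                    tps.append(hrvmod.time_domain(nn_t).log_sdnn)
                if ok:
                    repeated_rows.append(dict(
                        subject_id=s.subject_id, baseline=tps[0],
                        post=tps[1], month=tps[2]))
        hrv_rows.append(row)

    tfa_df = pd.DataFrame(tfa_rows)
    hrv_df = pd.DataFrame(hrv_rows)
    manifest = cohort.manifest

    demo_rows = [_group_anova_rows(manifest, ["age"]).assign(kind="anova")]
    labels = list(dict.fromkeys(manifest["group"]))
    for var in ("male", "hypertension", "hyperlipidemia", "diabetes",
                "smoking"):
        counts = np.array(
            [[manifest.loc[manifest.group == lab, var].sum(),
              (1 - manifest.loc[manifest.group == lab, var]).sum()]
             for lab in labels], dtype=float)
        try:
            res = statsmod.pearson_chi_square(counts)
        except ValueError:
            continue
        demo_rows.append(pd.DataFrame([dict(
            variable=var, method=res.method, statistic=res.statistic,
            df1=res.df[0], df2=np.nan, p=res.p, kind="chi2",
            **{f"{lab}_n": int(counts[i].sum()) for i, lab in enumerate(labels)},
        )]))
    demographics = pd.concat(demo_rows, ignore_index=True)

    tfa_groups = _group_anova_rows(
        tfa_df[tfa_df.valid],
        ["phase_overall", "phase_left", "phase_right",
         "gain_overall", "gain_left", "gain_right"])
    hrv_groups = _group_anova_rows(
        hrv_df[~hrv_df.excluded],
        ["mean_nn", "log_sdnn", "log_rmssd", "log_tp", "log_vlf",
         "log_lf", "log_hf", "nlf", "nhf", "lf_hf"])

    repeated = pd.DataFrame()
    if repeated_rows:
        mat = pd.DataFrame(repeated_rows)[["baseline", "post", "month"]].to_numpy()
        results = statsmod.repeated_measures_compare(mat)
        names = ["overall", "baseline_vs_post", "baseline_vs_month",
                 "post_vs_month"]
        repeated = pd.DataFrame([
            dict(contrast=nm, method=r.method, statistic=r.statistic, p=r.p,
                 n=mat.shape[0])
            for nm, r in zip(names, results)])

    for g in labels:
        log.info("group %s: %d analyzed for autoregulation, %d for HRV "
                 "(%d excluded)", g,
                 int((tfa_df.group == g).sum()),
                 int(((hrv_df.group == g) & (~hrv_df.excluded)).sum()),
                 excluded_by_group.get(g, 0))

    return StudyTables(
        demographics=demographics, tfa_subjects=tfa_df, tfa_groups=tfa_groups,
        hrv_subjects=hrv_df, hrv_groups=hrv_groups, repeated=repeated,
        exclusions=excluded_by_group,
    )


def simulated_phase_anova(spec: CohortSpec, seed: int,
                          tfa_cfg: TFAConfig = TFAConfig()) -> statsmod.TestResult:
    """One full simulate-and-estimate cycle reduced to the group contrast.

    Generates each subject's ABP and one CBFV channel, runs the transfer
    function analysis, and returns the one-way ANOVA over the estimated
    phases. This is the single-endpoint path used for power and type-I
    calibration of the end-to-end pipeline.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    samples = []
    for g in spec.groups:
        phases = []
        for _ in range(g.n):
            seeds = rng.integers(0, _MAX_SEED, size=2)
            abp = generate_abp(ABPSpec(duration_s=spec.duration_s, fs=spec.fs,
                                       seed=int(seeds[0])))
            target = _truncated_normal(rng, g.phase_mean_deg, g.phase_sd_deg,
                                       5.0, 85.0)
            filt = AutoregFilterSpec.lead_for_phase(
                target, spec.band_centre_hz, dc_gain=g.dc_gain,
                noise_sd=g.cbfv_noise_sd, noise_seed=int(seeds[1]))
            res = tfamod.analyze_pair(abp, apply_autoreg_filter(abp, filt),
                                      tfa_cfg)
            if res.valid:
                phases.append(res.phase_deg)
        samples.append(phases)
    return statsmod.anova_raw(samples)
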