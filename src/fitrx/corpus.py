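"""Training-corpus construction by Gaussian augmentation of study summaries.

The literature on exercise interventions for older adults is available
only as study-level summary statistics (mean +/- SD of age, BMI and
baseline VO2max, plus the prescription each study applied).  To obtain
subject-level training data, each study row is expanded into
``n_subjects`` synthetic subjects whose age, BMI and baseline VO2max are
drawn independently from Normal(mean, sd); sex and the achieved VO2max
improvement are held fixed at the study's values, and every synthetic
subject inherits the study's encoded prescription as its target.

Draws that would violate positivity (negative BMI, etc.) are rejected
and redrawn; at realistic summary statistics this is vanishingly rare,
so the sample moments remain effectively unbiased.  Each study gets its
own child RNG stream keyed by the global seed and a stable hash of the
study id, so reordering the study table never changes per-study content.

The module also provides fully synthetic study tables (standing in for a
literature supplement) and labelled response surfaces with a known
generating function, used for parameter-recovery testing.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .encoding import (
    EncodedSample,
    Prescription,
    SubjectProfile,
    encode_prescription,
    encode_subject,
)

__all__ = [
    "StudyRecord",
    "Corpus",
    "augment_study",
    "build_corpus",
    "synth_study_table",
    "synth_response_surface",
    "study_rng",
    "read_study_table",
    "write_study_table",
    "write_corpus",
    "read_corpus",
    "STUDY_TABLE_COLUMNS",
]

STUDY_TABLE_COLUMNS = [
    "study_id",
    "n_subjects",
    "age_mean",
    "age_sd",
    "bmi_mean",
    "bmi_sd",
    "vo2_mean",
    "vo2_sd",
    "prop_male",
    "improvement",
    "frequency",
    "intensity_pct_hrr",
    "time_min",
    "volume_wk",
]


@dataclass(frozen=True)
class StudyRecord:
    """Summary statistics and prescription of one included study.

    ``prop_male`` is the proportion of male subjects (0 or 1 for
    single-sex studies, in between for mixed cohorts); ``improvement``
    is the study's mean VO2max gain as a fraction of baseline.
    """

    study_id: str
    n_subjects: int
    age_mean: float
    age_sd: float
    bmi_mean: float
    bmi_sd: float
    vo2_mean: float
    vo2_sd: float
    prop_male: float
    improvement: float
    prescription: Prescription

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if min(self.age_sd, self.bmi_sd, self.vo2_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if min(self.age_mean, self.bmi_mean, self.vo2_mean) <= 0:
            raise ValueError("means must be positive")
        if not 0 <= self.prop_male <= 1:
            raise ValueError("prop_male must lie in [0, 1]")


@dataclass
class Corpus:
    """Encoded training corpus: X is (n, 5), Y is (n, 4)."""

    X: np.ndarray
    Y: np.ndarray
    provenance: list[str]
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if len(self.X) != len(self.Y) or len(self.X) != len(self.provenance):
            raise ValueError("X, Y and provenance must have equal length")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def samples(self) -> list[EncodedSample]:
        return [
            EncodedSample(x, y, sid)
            for x, y, sid in zip(self.X, self.Y, self.provenance)
        ]


def study_rng(seed: int, study_id: str) -> np.random.Generator:
    """Child RNG stream for one study, stable under table reordering."""
    key = zlib.crc32(study_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def _positive_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal draws with rejection of values that would not stay positive
    after the canonical 1-decimal rounding (i.e. anything below 0.05)."""
    out = rng.normal(mean, sd, size=n)
    bad = out < 0.05
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out < 0.05
    return out


def augment_study(rec: StudyRecord, rng: np.random.Generator) -> list[EncodedSample]:
    """Expand one study row into ``rec.n_subjects`` encoded samples.

    Per subject, (age, bmi, vo2_pre) is a 1x3 Gaussian draw around the
    study means; sex is assigned by a Bernoulli(prop_male) draw (fixed
    for single-sex studies); improvement and the target prescription are
    the study's fixed values.
    """
    n = rec.n_subjects
    ages = _positive_normal(rng, rec.age_mean, rec.age_sd, n)
    bmis = _positive_normal(rng, rec.bmi_mean, rec.bmi_sd, n)
    vo2s = _positive_normal(rng, rec.vo2_mean, rec.vo2_sd, n)
    if rec.prop_male in (0.0, 1.0):
        sexes = np.full(n, int(rec.prop_male))
    else:
        sexes = (rng.random(n) < rec.prop_male).astype(int)
    y = encode_prescription(rec.prescription)
    samples = []
    for i in range(n):
        profile = SubjectProfile(
            age=float(ages[i]),
            sex=int(sexes[i]),
            bmi=float(bmis[i]),
            vo2_pre=float(vo2s[i]),
            improvement=rec.improvement,
        )
        samples.append(EncodedSample(encode_subject(profile), y, rec.study_id))
    return samples


def build_corpus(table: Sequence[StudyRecord], seed: int) -> Corpus:
    """Concatenate per-study augmentation over the whole table.

    The corpus size always equals the sum of the table's subject counts.
    """
    if len(table) == 0:
        raise ValueError("study table is empty")
    xs, ys, prov = [], [], []
    for rec in table:
        for s in augment_study(rec, study_rng(seed, rec.study_id)):
            xs.append(s.x)
            ys.append(s.y)
            prov.append(rec.study_id)
    return Corpus(np.array(xs), np.array(ys), prov, rng_seed=seed)


def synth_study_table(
    k_studies: int,
    rng: np.random.Generator,
    total_subjects: int | None = None,
) -> list[StudyRecord]:
    """Draw a plausible synthetic study table.

    Ranges reflect intervention studies in older adults: age means
    60-80 y (SD 2-7), BMI means 21-30 kg/m^2 (SD 1-4), baseline VO2max
    means 10-35 mL.kg-1.min-1 (SD 1-5), improvement 5-20 %, frequency
    2-5 d/wk, intensity 50-80 %HRR, time 20-60 min, volume 8-24 wk,
    10-40 subjects per study.  ``total_subjects`` pins the column sum of
    ``n_subjects`` (e.g. 1,594 to match the corpus scale of the source
    literature).
    """
    if k_studies < 1:
        raise ValueError("k_studies must be >= 1")
    ns = rng.integers(10, 41, size=k_studies)
    if total_subjects is not None:
        if total_subjects < k_studies:
            raise ValueError("total_subjects must be >= k_studies")
        # rescale then distribute the remainder one subject at a time
        ns = np.maximum(1, (ns * total_subjects / ns.sum()).astype(int))
        while ns.sum() > total_subjects:
            ns[int(rng.integers(k_studies))] -= 1
            ns = np.maximum(1, ns)
        while ns.sum() < total_subjects:
            ns[int(rng.integers(k_studies))] += 1
    records = []
    for k in range(k_studies):
        intensity = float(rng.uniform(50, 80))
        rx = Prescription(
            frequency=int(rng.integers(2, 6)),
            intensity=intensity,
            time=float(np.round(rng.uniform(20, 60), 2)),
            volume=float(np.round(rng.uniform(8, 24), 2)),
            intensity_range=(intensity - 5, intensity + 5),
        )
        records.append(
            StudyRecord(
                study_id=f"S{k + 1:03d}",
                n_subjects=int(ns[k]),
                age_mean=float(np.round(rng.uniform(60, 80), 1)),
                age_sd=float(np.round(rng.uniform(2, 7), 1)),
                bmi_mean=float(np.round(rng.uniform(21, 30), 1)),
                bmi_sd=float(np.round(rng.uniform(1, 4), 1)),
                vo2_mean=float(np.round(rng.uniform(10, 35), 1)),
                vo2_sd=float(np.round(rng.uniform(1, 5), 1)),
                prop_male=float(rng.choice([0.0, 1.0, 0.5])),
                improvement=float(np.round(rng.uniform(0.05, 0.20), 2)),
                prescription=rx,
            )
        )
    return records


def _default_surface(X: np.ndarray) -> np.ndarray:
    """Smooth nonlinear map from subject features to prescription codes.

    Intensity decreases with BMI and age, time increases with the
    improvement target — monotone structure that recovery tests probe.
    """
    age, sex, bmi, vo2, imp = (X[:, j] for j in range(5))
    za = (age - 70.0) / 10.0
    zb = (bmi - 25.5) / 4.5
    zv = (vo2 - 22.5) / 12.5
    zi = (imp - 0.125) / 0.075
    freq = 3.0 + np.tanh(zi + 0.3 * zv)
    code = 0.12 - 0.15 * np.tanh(0.8 * zb + 0.5 * za) - 0.02 * sex
    time = 40.0 + 12.0 * np.tanh(zi - 0.4 * zv) + 3.0 * sex
    vol = 14.0 + 5.0 * np.tanh(0.6 * zi + 0.3 * za)
    return np.column_stack([freq, code, time, vol])


def synth_response_surface(
    n_samples: int,
    rng: np.random.Generator,
    noise_sd: float = 0.0,
    fn: Callable[[np.ndarray], np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, Callable[[np.ndarray], np.ndarray]]:
    """Labelled corpus (X, Y) from a known response surface.

    Inputs are drawn uniformly over realistic subject ranges; targets
    are ``fn(X)`` plus iid Gaussian noise of SD ``noise_sd`` on every
    output.  The generating function is returned so tests can measure
    recovery against ground truth.
    """
    fn = fn if fn is not None else _default_surface
    X = np.column_stack(
        [
            rng.uniform(60, 80, n_samples),
            rng.integers(0, 2, n_samples).astype(float),
            rng.uniform(21, 30, n_samples),
            rng.uniform(10, 35, n_samples),
            rng.uniform(0.05, 0.20, n_samples),
        ]
    )
    Y = fn(X)
    if noise_sd > 0:
        Y = Y + rng.normal(0.0, noise_sd, size=Y.shape)
    return X, Y, fn


def synth_teacher_corpus(
    n_samples: int,
    rng: np.random.Generator,
    sizes: tuple[int, ...] = (5, 12, 10, 8, 4),
    weight_scale: float = 1.5,
):
    """Noise-free corpus generated by a random same-architecture network.

    Inputs live on the standardized scale (uniform in [-1, 1]^5, roughly
    what z-scored subject features span), so the target function is
    exactly realizable by the model class — the ground truth for
    convergence and recovery tests.  Returns (X, Y, teacher_state).
    """
    from .network import LayerSpec, NetworkState, forward_batch, init_network

    teacher = init_network(LayerSpec(sizes=sizes), rng)
    teacher = NetworkState(
        teacher.spec,
        [weight_scale * W for W in teacher.weights],
        [b.copy() for b in teacher.biases],
    )
    X = rng.uniform(-1.0, 1.0, size=(n_samples, sizes[0]))
    return X, forward_batch(teacher, X), teacher


# ---------------------------------------------------------------------------
# file round-tripping

def write_study_table(table: Sequence[StudyRecord], path: str | Path) -> None:
    rows = []
    for r in table:
        rows.append(
            {
                "study_id": r.study_id,
                "n_subjects": r.n_subjects,
                "age_mean": r.age_mean,
                "age_sd": r.age_sd,
                "bmi_mean": r.bmi_mean,
                "bmi_sd": r.bmi_sd,
                "vo2_mean": r.vo2_mean,
                "vo2_sd": r.vo2_sd,
                "prop_male": r.prop_male,
                "improvement": r.improvement,
                "frequency": r.prescription.frequency,
                "intensity_pct_hrr": r.prescription.intensity,
                "time_min": r.prescription.time,
                "volume_wk": r.prescription.volume,
            }
        )
    pd.DataFrame(rows, columns=STUDY_TABLE_COLUMNS).to_csv(path, index=False)


def read_study_table(path: str | Path) -> list[StudyRecord]:
    df = pd.read_csv(path)
    missing = set(STUDY_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"study table missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        rx = Prescription(
            frequency=float(row["frequency"]),
            intensity=float(row["intensity_pct_hrr"]),
            time=float(row["time_min"]),
            volume=float(row["volume_wk"]),
        )
        records.append(
            StudyRecord(
                study_id=str(row["study_id"]),
                n_subjects=int(row["n_subjects"]),
                age_mean=float(row["age_mean"]),
                age_sd=float(row["age_sd"]),
                bmi_mean=float(row["bmi_mean"]),
                bmi_sd=float(row["bmi_sd"]),
                vo2_mean=float(row["vo2_mean"]),
                vo2_sd=float(row["vo2_sd"]),
                prop_male=float(row["prop_male"]),
                improvement=float(row["improvement"]),
                prescription=rx,
            )
        )
    return records


def write_corpus(corpus: Corpus, csv_path: str | Path, sidecar_path: str | Path | None = None) -> None:
    """Corpus as a CSV of encoded vectors plus a JSON sidecar (seed, provenance)."""
    cols_x = ["age", "sex", "bmi", "vo2_pre", "improvement"]
    cols_y = ["frequency", "intensity_code", "time_min", "volume_wk"]
    df = pd.DataFrame(np.hstack([corpus.X, corpus.Y]), columns=cols_x + cols_y)
    df.insert(0, "study_id", corpus.provenance)
    df.to_csv(csv_path, index=False)
    if sidecar_path is not None:
        sidecar = {
            "rng_seed": corpus.rng_seed,
            "n_samples": len(corpus),
            "studies": sorted(set(corpus.provenance)),
        }
        Path(sidecar_path).write_text(json.dumps(sidecar, indent=2) + "\n")


def read_corpus(csv_path: str | Path, sidecar_path: str | Path | None = None) -> Corpus:
    df = pd.read_csv(csv_path)
    X = df[["age", "sex", "bmi", "vo2_pre", "improvement"]].to_numpy(float)
    Y = df[["frequency", "intensity_code", "time_min", "volume_wk"]].to_numpy(float)
    seed = None
    if sidecar_path is not None and Path(sidecar_path).exists():
        seed = json.loads(Path(sidecar_path).read_text()).get("rng_seed")
    return Corpus(X, Y, [str(s) for s in df["study_id"]], rng_seed=seed)
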