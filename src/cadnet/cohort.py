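"""Seeded synthetic cohort generator.

The real study paired resting thoracic phase signals with coronary
angiography in 606 subjects (512 development = 339 training + 173
validation, plus 94 naive verification), with roughly 31% of subjects
CAD-positive by the protocol rule.  The signal features themselves are
proprietary, so this module generates a cohort with the *statistical
structure* the analysis pipeline assumes:

* per-subject angiograms (lesion lists with stenosis, segment, optional
  FFR, collaterals) whose lesion-rate is calibrated analytically so the
  cohort prevalence of protocol-positive CAD matches ``prevalence_target``;
* demographics matched to the development-cohort summary moments
  (age ~ N(61.5, 10.7) truncated to [21, 95], 60.2% male,
  BMI ~ N(31.3, 7.0) truncated at 15);
* a per-acquisition noise volume ~ LogNormal(0, 0.5), a stand-in for the
  device's environmental-contamination scalar;
* a block-equicorrelated feature matrix (shared latent factor per block,
  within-block correlation 0.95) in which ``n_informative`` features carry
  a planted linear signal proportional to the standardized modified Gensini
  score, and all structured noise is scaled per subject by
  ``1 + noise_volume * noise_scale`` so noisy acquisitions are genuinely
  less informative.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .gensini import SEGMENTS, AngiogramRecord, GensiniConfig, Lesion, modified_gensini

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "simulate_angiogram",
    "simulate_features",
    "simulate_cohort",
    "assign_splits",
    "write_cohort",
    "read_cohort",
    "features_matrix",
    "cohort_frame",
]

SPLITS = ("train", "validation", "verification")

# --- angiogram model constants (stipulations; the study reports no
#     angiographic lesion-count or location distribution) ---------------
_MEAN_EXTRA_LESIONS = 0.8       # lesion count = 1 + Poisson(mu) when diseased
_P_CRITICAL = 0.5               # critical lesion: stenosis ~ U[70, 100]
_SUBCRIT_RANGE = (20.0, 65.0)   # sub-critical: stenosis ~ U[20, 65]
_CRIT_RANGE = (70.0, 100.0)
_FFR_RANGE = (40.0, 70.0)       # flow-wire assessment window
_P_FFR_MEASURED = 0.5
_FFR_SLOPE = -0.005             # mean FFR = 1.05 - 0.005 * stenosis
_FFR_INTERCEPT = 1.05
_FFR_SD = 0.04
_P_COLLATERALS = 0.2            # given any lesion >= 90%
_SEGMENT_PROBS = {
    "LM": 0.03, "pLAD": 0.12, "mLAD": 0.12, "dLAD": 0.10, "pLCx": 0.12,
    "OM": 0.12, "RCA": 0.20, "PDA": 0.09, "OTHER": 0.10,
}

# demographics: development-cohort moments
_AGE = (61.5, 10.7, 21.0, 95.0)
_MALE_FRACTION = 0.602
_BMI = (31.3, 7.0, 15.0, np.inf)
_HEART_RATE = (70.0, 12.0, 40.0, 130.0)
_NOISE_LOGNORMAL = (0.0, 0.5)


def _p_lesion_positive() -> float:
    """Probability that a single simulated lesion is protocol-positive.

    Critical lesions (stenosis >= 70, never flow-wired) are always positive.
    A sub-critical lesion is positive only via a measured FFR <= 0.80;
    the FFR mean falls linearly with stenosis, so the tail probability is
    the average of a normal CDF over the uniform stenosis range.
    """
    lo, hi = _SUBCRIT_RANGE
    flo, fhi = max(_FFR_RANGE[0], lo), min(_FFR_RANGE[1], hi)
    p_in_window = (fhi - flo) / (hi - lo)
    # average over s ~ U[flo, fhi] of P(FFR <= 0.80)
    z = lambda s: (0.80 - (_FFR_INTERCEPT + _FFR_SLOPE * s)) / _FFR_SD
    za, zb = z(flo), z(fhi)
    # closed form: int Phi(z) dz = z Phi(z) + phi(z)
    integral = (zb * norm.cdf(zb) + norm.pdf(zb)) - (za * norm.cdf(za) + norm.pdf(za))
    p_ffr_pos = integral / (zb - za)
    p_sub_pos = p_in_window * _P_FFR_MEASURED * p_ffr_pos
    return _P_CRITICAL + (1.0 - _P_CRITICAL) * p_sub_pos


def _p_positive_given_diseased() -> float:
    """P(subject positive | at least one lesion) under 1 + Poisson(mu) lesions."""
    pl = _p_lesion_positive()
    return 1.0 - (1.0 - pl) * math.exp(-_MEAN_EXTRA_LESIONS * pl)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort sizes, feature geometry and signal/noise knobs.

    Defaults reproduce the study's conditions: 606 subjects split
    339/173/94, 405 features in 40 equicorrelated blocks, ~31% prevalence.
    """

    n_total: int = 606
    n_dev: int = 512
    n_train: int = 339
    n_val: int = 173
    n_verif: int = 94
    n_features: int = 405
    n_informative: int = 10
    n_blocks: int = 40
    within_block_corr: float = 0.95
    signal_strength: float = 1.0
    prevalence_target: float = 0.31
    noise_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train + self.n_val != self.n_dev:
            raise ValueError("n_train + n_val must equal n_dev")
        if self.n_dev + self.n_verif != self.n_total:
            raise ValueError("n_dev + n_verif must equal n_total")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative must not exceed n_features")
        if not 0.0 <= self.within_block_corr < 1.0:
            raise ValueError("within_block_corr must be in [0, 1)")
        if not 0.0 <= self.prevalence_target < 1.0:
            raise ValueError("prevalence_target must be in [0, 1)")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be nonnegative")
        if self.n_blocks < 1 or self.n_blocks > self.n_features:
            raise ValueError("n_blocks must be in [1, n_features]")


@dataclass
class SubjectRecord:
    subject_id: str
    split: str | None
    age: float
    sex: str  # "male" | "female"
    heart_rate: float
    bmi: float
    angiogram: AngiogramRecord
    noise_volume: float
    cad: bool
    gensini_modified: float
    features: np.ndarray | None = None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SubjectRecord):
            return NotImplemented
        same_features = (
            (self.features is None and other.features is None)
            or (
                self.features is not None
                and other.features is not None
                and np.array_equal(self.features, other.features)
            )
        )
        return same_features and all(
            getattr(self, f) == getattr(other, f)
            for f in (
                "subject_id", "split", "age", "sex", "heart_rate", "bmi",
                "angiogram", "noise_volume", "cad", "gensini_modified",
            )
        )


# --------------------------------------------------------------------------
# angiogram simulation

def _draw_lesion(rng: np.random.Generator) -> Lesion:
    if rng.random() < _P_CRITICAL:
        stenosis = rng.uniform(*_CRIT_RANGE)
    else:
        stenosis = rng.uniform(*_SUBCRIT_RANGE)
    segment = str(rng.choice(SEGMENTS, p=[_SEGMENT_PROBS[s] for s in SEGMENTS]))
    ffr = None
    measured = False
    if _FFR_RANGE[0] <= stenosis < _FFR_RANGE[1] and rng.random() < _P_FFR_MEASURED:
        measured = True
        ffr = float(
            np.clip(
                _FFR_INTERCEPT + _FFR_SLOPE * stenosis + rng.normal(0.0, _FFR_SD),
                0.05,
                1.0,
            )
        )
    return Lesion(stenosis=float(stenosis), segment=segment, ffr=ffr, ffr_measured=measured)


def draw_collaterals(lesions: tuple[Lesion, ...], rng: np.random.Generator) -> bool:
    """Collaterals appear with probability 0.2 given any lesion >= 90% stenosis."""
    if any(l.stenosis >= 90.0 for l in lesions):
        return bool(rng.random() < _P_COLLATERALS)
    return False


def simulate_angiogram(config: CohortConfig, rng: np.random.Generator) -> AngiogramRecord:
    """One subject's catheterization findings.

    The lesion-free probability is solved analytically from
    ``prevalence_target`` and the per-lesion positivity rate implied by the
    stenosis/FFR model, so the cohort-level CAD-positive fraction lands on
    the target (within Monte-Carlo error) without empirical tuning.
    """
    p_pos_given_diseased = _p_positive_given_diseased()
    p_diseased = min(config.prevalence_target / p_pos_given_diseased, 1.0)
    if rng.random() >= p_diseased:
        return AngiogramRecord(lesions=(), collaterals_present=False)
    n_lesions = 1 + rng.poisson(_MEAN_EXTRA_LESIONS)
    lesions = tuple(_draw_lesion(rng) for _ in range(n_lesions))
    return AngiogramRecord(
        lesions=lesions, collaterals_present=draw_collaterals(lesions, rng)
    )


# --------------------------------------------------------------------------
# demographics, noise, features

def _trunc_normal(rng, mean, sd, lo, hi) -> float:
    while True:
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)


def _informative_indices(config: CohortConfig) -> np.ndarray:
    """Planted-signal columns: the first member of each block, cycling to
    later members if there are more informative features than blocks."""
    blocks = np.array_split(np.arange(config.n_features), config.n_blocks)
    idx = []
    depth = 0
    while len(idx) < config.n_informative:
        for b in blocks:
            if depth < len(b):
                idx.append(int(b[depth]))
                if len(idx) == config.n_informative:
                    break
        depth += 1
    return np.asarray(idx, dtype=int)


def simulate_features(
    subjects: list[SubjectRecord], config: CohortConfig, rng: np.random.Generator
) -> np.ndarray:
    """Block-equicorrelated feature matrix with a planted Gensini signal.

    feature_ij = signal_strength * g_i * [j informative]
                 + (1 + noise_volume_i * noise_scale)
                   * (sqrt(rho) * z_{i,block(j)} + sqrt(1-rho) * eps_ij)

    where g is the cohort-standardized modified Gensini score.  Scaling the
    whole structured-noise term per subject keeps within-block correlations
    at ``rho`` exactly while degrading the signal-to-noise ratio of noisy
    acquisitions.  Also attaches the rows to ``subjects[i].features``.
    """
    n = len(subjects)
    if n == 0:
        raise ValueError("empty subject list")
    p = config.n_features
    g = np.array([s.gensini_modified for s in subjects])
    sd = g.std()
    g = (g - g.mean()) / sd if sd > 0 else np.zeros(n)

    blocks = np.array_split(np.arange(p), config.n_blocks)
    block_of = np.empty(p, dtype=int)
    for b, cols in enumerate(blocks):
        block_of[cols] = b

    rho = config.within_block_corr
    z = rng.standard_normal((n, config.n_blocks))
    eps = rng.standard_normal((n, p))
    noise = math.sqrt(rho) * z[:, block_of] + math.sqrt(1.0 - rho) * eps
    sigma = 1.0 + np.array([s.noise_volume for s in subjects]) * config.noise_scale

    X = sigma[:, None] * noise
    X[:, _informative_indices(config)] += config.signal_strength * g[:, None]
    for i, s in enumerate(subjects):
        s.features = X[i]
    return X


# --------------------------------------------------------------------------
# splits

def assign_splits(
    subjects: list[SubjectRecord], config: CohortConfig, rng: np.random.Generator
) -> list[SubjectRecord]:
    """Random split assignment, stratified by CAD label, with exact counts
    (n_train, n_val, n_verif).  Class quotas per split use the largest-
    remainder method so train/validation prevalences agree closely."""
    if len(subjects) != config.n_total:
        raise ValueError(f"expected {config.n_total} subjects, got {len(subjects)}")
    sizes = np.array([config.n_train, config.n_val, config.n_verif])
    labels = np.array([s.cad for s in subjects])
    assignment = np.empty(len(subjects), dtype=object)

    remaining = sizes.copy()
    for positive in (True, False):
        idx = np.where(labels == positive)[0]
        rng.shuffle(idx)
        if positive:
            quota_f = sizes * (idx.size / config.n_total)
            quota = np.floor(quota_f).astype(int)
            frac_order = np.argsort(-(quota_f - quota))
            for k in frac_order:
                if quota.sum() == idx.size:
                    break
                quota[k] += 1
            quota = np.minimum(quota, remaining)
            # largest-remainder can leave a unit unplaced after capping
            while quota.sum() < idx.size:
                k = int(np.argmax(remaining - quota))
                quota[k] += 1
        else:
            quota = remaining.copy()
        start = 0
        for split_name, q in zip(SPLITS, quota):
            assignment[idx[start : start + q]] = split_name
            start += q
        remaining = remaining - quota

    for s, split_name in zip(subjects, assignment):
        s.split = str(split_name)
    return subjects


# --------------------------------------------------------------------------
# top-level generation

def simulate_cohort(
    config: CohortConfig, gensini_config: GensiniConfig | None = None
) -> list[SubjectRecord]:
    """Generate the full seeded cohort: angiograms, labels and Gensini
    targets, demographics, noise volumes, splits and the feature matrix."""
    gcfg = gensini_config if gensini_config is not None else GensiniConfig()
    rng = np.random.default_rng(config.seed)
    subjects: list[SubjectRecord] = []
    width = len(str(config.n_total))
    for i in range(config.n_total):
        angio = simulate_angiogram(config, rng)
        result = modified_gensini(angio, gcfg)
        subjects.append(
            SubjectRecord(
                subject_id=f"S{i + 1:0{width}d}",
                split=None,
                age=_trunc_normal(rng, *_AGE),
                sex="male" if rng.random() < _MALE_FRACTION else "female",
                heart_rate=_trunc_normal(rng, *_HEART_RATE),
                bmi=_trunc_normal(rng, *_BMI),
                angiogram=angio,
                noise_volume=float(rng.lognormal(*_NOISE_LOGNORMAL)),
                cad=result.cad_positive,
                gensini_modified=result.modified_score,
            )
        )
    assign_splits(subjects, config, rng)
    simulate_features(subjects, config, rng)
    return subjects


# --------------------------------------------------------------------------
# tabular views and CSV round trip

def features_matrix(subjects: list[SubjectRecord]) -> np.ndarray:
    """Model design matrix: the signal features with age, sex code
    (1 = male) and heart rate appended as the last three columns."""
    X = np.stack([s.features for s in subjects])
    demo = np.array([[s.age, 1.0 if s.sex == "male" else 0.0, s.heart_rate] for s in subjects])
    return np.hstack([X, demo])


def cohort_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "split": [s.split for s in subjects],
            "age": [s.age for s in subjects],
            "sex": [s.sex for s in subjects],
            "heart_rate": [s.heart_rate for s in subjects],
            "bmi": [s.bmi for s in subjects],
            "noise_volume": [s.noise_volume for s in subjects],
            "collaterals": [int(s.angiogram.collaterals_present) for s in subjects],
            "n_lesions": [len(s.angiogram.lesions) for s in subjects],
            "cad_label": [int(s.cad) for s in subjects],
            "gensini_modified": [s.gensini_modified for s in subjects],
        }
    )


_COHORT_COLUMNS = [
    "subject_id", "split", "age", "sex", "heart_rate", "bmi",
    "noise_volume", "collaterals", "n_lesions", "cad_label", "gensini_modified",
]
_LESION_COLUMNS = ["subject_id", "stenosis_pct", "segment", "ffr_measured", "ffr"]


def _feature_names(p: int) -> list[str]:
    width = max(3, len(str(p)))
    return [f"f{j + 1:0{width}d}" for j in range(p)]


def write_cohort(subjects: list[SubjectRecord], cohort_path, lesions_path, features_path) -> None:
    """Write the three-file CSV representation (cohort, lesions, features)."""
    cohort_frame(subjects).to_csv(cohort_path, index=False, float_format="%.17g")

    rows = []
    for s in subjects:
        for lesion in s.angiogram.lesions:
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "stenosis_pct": lesion.stenosis,
                    "segment": lesion.segment,
                    "ffr_measured": int(lesion.ffr_measured),
                    "ffr": lesion.ffr if lesion.ffr is not None else "",
                }
            )
    pd.DataFrame(rows, columns=_LESION_COLUMNS).to_csv(
        lesions_path, index=False, float_format="%.17g"
    )

    p = subjects[0].features.shape[0]
    feat = pd.DataFrame(
        np.stack([s.features for s in subjects]), columns=_feature_names(p)
    )
    feat.insert(0, "subject_id", [s.subject_id for s in subjects])
    feat["age"] = [s.age for s in subjects]
    feat["sex_code"] = [1 if s.sex == "male" else 0 for s in subjects]
    feat["heart_rate"] = [s.heart_rate for s in subjects]
    feat.to_csv(features_path, index=False, float_format="%.17g")


class CohortParseError(ValueError):
    pass


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortParseError(f"{path}: missing column(s) {missing}")


def read_cohort(cohort_path, lesions_path, features_path) -> list[SubjectRecord]:
    """Read the three-file representation back into subject records.

    Validates the schema (a missing column is an error, never a silent
    default) and names the offending row and column on malformed values.
    """
    cohort = pd.read_csv(cohort_path, dtype={"subject_id": str}, float_precision="round_trip")
    _require_columns(cohort, _COHORT_COLUMNS, cohort_path)
    lesions = pd.read_csv(lesions_path, dtype={"subject_id": str}, float_precision="round_trip")
    _require_columns(lesions, _LESION_COLUMNS, lesions_path)
    features = pd.read_csv(features_path, dtype={"subject_id": str}, float_precision="round_trip")
    feature_cols = [c for c in features.columns if c.startswith("f") and c[1:].isdigit()]
    _require_columns(features, ["subject_id", "age", "sex_code", "heart_rate"], features_path)
    if not feature_cols:
        raise CohortParseError(f"{features_path}: no feature columns (f###) found")

    def cell(df, row, col, cast, path):
        try:
            return cast(df.at[row, col])
        except (TypeError, ValueError) as exc:
            raise CohortParseError(f"{path}: row {row}, column {col!r}: {exc}") from None

    lesions_by_subject: dict[str, list[Lesion]] = {}
    for row in lesions.index:
        sid = lesions.at[row, "subject_id"]
        measured = bool(cell(lesions, row, "ffr_measured", int, lesions_path))
        ffr_raw = lesions.at[row, "ffr"]
        ffr = None
        if measured:
            ffr = cell(lesions, row, "ffr", float, lesions_path)
            if np.isnan(ffr):
                raise CohortParseError(
                    f"{lesions_path}: row {row}, column 'ffr': missing for measured lesion"
                )
        lesions_by_subject.setdefault(sid, []).append(
            Lesion(
                stenosis=cell(lesions, row, "stenosis_pct", float, lesions_path),
                segment=str(lesions.at[row, "segment"]),
                ffr=ffr,
                ffr_measured=measured,
            )
        )

    feat_by_subject = features.set_index("subject_id")
    subjects = []
    for row in cohort.index:
        sid = cohort.at[row, "subject_id"]
        split = cohort.at[row, "split"]
        if split not in SPLITS:
            raise CohortParseError(
                f"{cohort_path}: row {row}, column 'split': unknown value {split!r}"
            )
        n_lesions = cell(cohort, row, "n_lesions", int, cohort_path)
        subject_lesions = tuple(lesions_by_subject.get(sid, []))
        if len(subject_lesions) != n_lesions:
            raise CohortParseError(
                f"{cohort_path}: row {row}: n_lesions={n_lesions} but "
                f"{len(subject_lesions)} lesion rows found for {sid}"
            )
        angio = AngiogramRecord(
            lesions=subject_lesions,
            collaterals_present=bool(cell(cohort, row, "collaterals", int, cohort_path)),
        )
        if sid not in feat_by_subject.index:
            raise CohortParseError(f"{features_path}: no feature row for subject {sid}")
        subjects.append(
            SubjectRecord(
                subject_id=str(sid),
                split=str(split),
                age=cell(cohort, row, "age", float, cohort_path),
                sex=str(cohort.at[row, "sex"]),
                heart_rate=cell(cohort, row, "heart_rate", float, cohort_path),
                bmi=cell(cohort, row, "bmi", float, cohort_path),
                angiogram=angio,
                noise_volume=cell(cohort, row, "noise_volume", float, cohort_path),
                cad=bool(cell(cohort, row, "cad_label", int, cohort_path)),
                gensini_modified=cell(cohort, row, "gensini_modified", float, cohort_path),
                features=feat_by_subject.loc[sid, feature_cols].to_numpy(dtype=float),
            )
        )
    return subjects
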