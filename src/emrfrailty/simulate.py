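"""Synthetic multi-table primary-care EMR cohorts with a plantable frailty signal.

Emulates the CPCSSN-style extract used for frailty case-definition work: one
patient demographics table plus satellite tables (billing, encounters,
encounter diagnoses, exams, labs, medications, referrals, risk factors,
disease-case indicators), and a per-patient Clinical Frailty Scale (CFS)
assessment by the patient's sentinel physician.

The generative model is a latent logistic liability: each patient carries
Bernoulli exposures to the planted signal features; liability is an intercept
(calibrated so the marginal frail fraction hits the target prevalence) plus
the exposure log-odds, an optional physician random effect, and standard
logistic noise.  The liability is mapped to the ordinal CFS 1-9 through fixed
thresholds, with liability > 0 corresponding exactly to CFS >= 5 ("frail").
Exposed patients receive a concrete EMR record for each planted feature (an
ICD-9 code, an ATC-coded medication, or a free-text token), so the signal is
recoverable only through the downstream feature-extraction rules.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "SignalFeature",
    "SimConfig",
    "EmrTables",
    "CfsAssessment",
    "generate_cohort",
    "write_tables",
    "read_tables",
    "write_assessments",
    "read_assessments",
    "TABLE_SCHEMAS",
    "DEFAULT_SIGNALS",
]

TABLE_SCHEMAS: dict[str, list[str]] = {
    "patient": ["patient_id", "sex", "birth_year"],
    "billing": ["patient_id", "date", "icd9_code", "diagnosis_text"],
    "encounter": ["patient_id", "date", "encounter_reason_text"],
    "encounter_diagnosis": ["patient_id", "date", "icd9_code", "diagnosis_text"],
    "exam": ["patient_id", "date", "measure_name", "value"],
    "lab": ["patient_id", "date", "analyte_name", "value", "unit"],
    "medication": ["patient_id", "date", "atc_code", "medication_name_text"],
    "referral": ["patient_id", "date", "referral_text"],
    "risk_factor": ["patient_id", "factor_name", "status"],
    "disease_case": ["patient_id", "condition"],
}

#: signal kinds understood by the generator, mapped to the table they plant into
SIGNAL_KINDS = {
    "billing_icd9": "billing",
    "encounter_diagnosis_icd9": "encounter_diagnosis",
    "medication_atc": "medication",
    "medication_word": "medication",
    "encounter_word": "encounter",
    "billing_word": "billing",
}

DISEASE_CONDITIONS = (
    "COPD",
    "dementia",
    "depression",
    "DM",
    "epilepsy",
    "hypertension",
    "osteoarthritis",
    "parkinsons",
)

# Background vocabularies.  Deliberately plain lowercase unigram-bearing short
# fields; numeric tokens appear through medication strengths.
_WORDS = (
    "pain chest knee hip back neck visit followup review annual exam checkup "
    "cough fever rash fatigue dizziness nausea hypertension hypotension diabetes "
    "arthritis joint swelling injection renewal meds refill discussion symptoms "
    "two three left right acute chronic mild severe nos not and mention unspecified "
    "screening assessment bloodwork results injury fall sprain fracture wound "
    "infection urinary respiratory cardiac skin lesion actinic keratosis mole "
    "anxiety depression sleep insomnia weight loss gain diet counselling referral "
    "immunization flu vaccine wellness senior mobility balance tremor memory "
    "confusion hearing vision cataract glaucoma constipation reflux ulcer anemia "
    "thyroid cholesterol lipid glucose pressure monitor recheck stable worsening "
    "improved medication adjustment dose increase decrease stop start trial "
    "physio therapy home care support family discussion consent form letter "
    "report note telephone call message lab requisition imaging xray ultrasound "
    "abdominal pelvic shoulder elbow wrist ankle foot toe finger hand swelling "
    "edema palpitations murmur bruit asthma copd emphysema bronchitis pneumonia "
    "sinusitis otitis vertigo migraine headache neuropathy sciatica stenosis "
    "osteoporosis vitamin deficiency b12 iron ferritin dehydration malaise"
).split()

_DRUG_NAMES = (
    "metformin ramipril amlodipine atorvastatin rosuvastatin hydrochlorothiazide "
    "furosemide bisoprolol metoprolol candesartan irbesartan gliclazide sitagliptin "
    "levothyroxine pantoprazole rabeprazole citalopram sertraline venlafaxine "
    "trazodone zopiclone gabapentin pregabalin acetaminophen naproxen celecoxib "
    "warfarin apixaban rivaroxaban clopidogrel tamsulosin finasteride alendronate "
    "risedronate salbutamol tiotropium budesonide prednisone cephalexin amoxicillin "
    "nitrofurantoin ciprofloxacin docusate lactulose erbumine perindopril"
).split()

_DRUG_FORMS = ("tablet", "capsule", "solution", "extended release tablet", "cream")
_DRUG_STRENGTHS = (5, 10, 20, 25, 40, 50, 75, 100, 250, 500, 850, 1000)

_ICD9_CODES = (
    "005 038.9 117 153.4 162.9 174.9 185 198.5 250.00 250.01 272.4 280.0 285.9 "
    "290.0 294.8 295.7 296.2 300.00 311 327.23 331.0 332.0 340 345.90 354.0 "
    "366.9 389.10 401.1 401.9 402.90 410.9 414.00 427.31 428.0 433.1 436 443.9 "
    "456.4 486 490 491.21 493.90 496 530.81 535.50 560.9 562.10 571.5 585.9 "
    "593.9 599.0 600.00 692.9 707.0 710.0 714.0 715.90 721.0 724.2 727.3 733.00 "
    "780.79 781.2 784.0 786.2 788.30 799.3 805 V04.81 V22.1 V49 V58.69 V70.0 V82"
).split()

_ATC_CODES = (
    "A01AB03 A02BC02 A06AD11 A10BA02 A10BB09 A11CC05 A12AX B01AA03 B01AC06 "
    "B03BA01 B05XA03 C01DA14 C03CA01 C03AA03 C07AB07 C08CA01 C09AA05 C10AA05 "
    "G04CA02 H03AA01 J01CA04 J01DB01 L04AX03 M01AE02 M05BA04 N02BE01 N05CF01 "
    "N06AB04 N06AX16 R03AC02 R03BB04 S01EE01 V07AB00"
).split()

_REFERRAL_TARGETS = (
    "cardiologist", "geriatrician", "diabetologist", "physiotherapy", "imaging",
    "neurologist", "ophthalmologist", "orthopedics", "social worker", "dietitian",
    "audiology", "urology", "home care", "respirology", "rheumatology",
)

_RISK_FACTORS = {
    "smoking": ("current", "former", "never", "unknown"),
    "alcohol": ("current", "former", "never", "unknown"),
    "exercise": ("sedentary", "moderate", "active", "unknown"),
}

# Lab analyte -> (log-mean, log-sd, unit).  Centred near the normal range so
# low/normal/high all occur.
_LAB_ANALYTES = {
    "creatinine": (np.log(85.0), 0.30, "umol/L"),
    "glucose_fasting": (np.log(5.6), 0.22, "mmol/L"),
    "hemoglobin": (np.log(140.0), 0.12, "g/L"),
    "tsh": (np.log(2.2), 0.55, "mU/L"),
}

_EXAM_MEASURES = {
    "bmi": (27.0, 4.5),
    "systolic_bp": (133.0, 16.0),
    "waist": (96.0, 13.0),
}

#: CFS thresholds on the latent liability; liability > 0  <=>  CFS >= 5
_CFS_THRESHOLDS = (-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0, 4.0)


@dataclass(frozen=True)
class SignalFeature:
    """One planted exposure: a feature identifier plus its frailty log-odds.

    ``kind`` selects the table/field (see :data:`SIGNAL_KINDS`); ``value`` is
    the planted content (a 3-character ICD-9 prefix, a level-2 ATC code, or a
    free-text token).  ``base_rate`` is the marginal exposure probability.
    """

    kind: str
    value: str
    log_odds: float
    base_rate: float = 0.15

    def __post_init__(self) -> None:
        if self.kind not in SIGNAL_KINDS:
            raise ValueError(
                f"unknown signal kind {self.kind!r}; known: {sorted(SIGNAL_KINDS)}"
            )
        if not 0.0 < self.base_rate < 1.0:
            raise ValueError("base_rate must be in (0, 1)")


#: signal set emulating the qualitative signature of a frail primary-care
#: cohort: a dementia diagnosis code, loop-diuretic prescriptions, vitamin
#: prescriptions, and a bowel-obstruction mention in billing text
DEFAULT_SIGNALS: tuple[SignalFeature, ...] = (
    SignalFeature("encounter_diagnosis_icd9", "290", 1.8, 0.12),
    SignalFeature("medication_atc", "C03", 1.2, 0.20),
    SignalFeature("medication_word", "vitamins", 1.0, 0.18),
    SignalFeature("billing_word", "obstruction", 0.8, 0.10),
)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic cohort (fully determined by ``seed``)."""

    n_physicians: int = 52
    patients_per_physician: int = 15
    target_prevalence: float = 0.177
    signal_spec: tuple[SignalFeature, ...] = DEFAULT_SIGNALS
    date_range: tuple[date, date] = (date(2015, 1, 1), date(2016, 12, 31))
    vocab_size: int = 120
    # mean background records per patient, per table
    rates: dict[str, float] = field(
        default_factory=lambda: {
            "billing": 6.0,
            "encounter": 8.0,
            "encounter_diagnosis": 6.0,
            "medication": 5.0,
            "lab": 4.0,
            "exam": 3.0,
            "referral": 1.0,
        }
    )
    physician_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_physicians <= 0 or self.patients_per_physician <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must lie strictly in (0, 1)")
        if self.date_range[0] >= self.date_range[1]:
            raise ValueError("date_range start must precede end")
        if self.vocab_size < 5:
            raise ValueError("vocab_size too small")
        object.__setattr__(self, "signal_spec", tuple(self.signal_spec))

    @property
    def n_patients(self) -> int:
        return self.n_physicians * self.patients_per_physician


@dataclass(frozen=True)
class CfsAssessment:
    """A physician's Clinical Frailty Scale score (1 very fit ... 9 terminally ill)."""

    patient_id: str
    physician_id: str
    cfs_score: int

    def __post_init__(self) -> None:
        if not 1 <= int(self.cfs_score) <= 9:
            raise ValueError(
                f"cfs_score must be in 1..9, got {self.cfs_score} "
                f"for patient {self.patient_id}"
            )


@dataclass
class EmrTables:
    """The multi-table EMR bundle; one DataFrame per CPCSSN-style table.

    Dates are ISO-8601 strings throughout (lexicographic order equals
    chronological order), which keeps CSV round-trips exact.
    """

    patient: pd.DataFrame
    billing: pd.DataFrame
    encounter: pd.DataFrame
    encounter_diagnosis: pd.DataFrame
    exam: pd.DataFrame
    lab: pd.DataFrame
    medication: pd.DataFrame
    referral: pd.DataFrame
    risk_factor: pd.DataFrame
    disease_case: pd.DataFrame

    def as_dict(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_SCHEMAS}

    def equals(self, other: "EmrTables") -> bool:
        for name in TABLE_SCHEMAS:
            a, b = getattr(self, name), getattr(other, name)
            if list(a.columns) != list(b.columns):
                return False
            if len(a) == 0 and len(b) == 0:
                continue
            if not a.reset_index(drop=True).equals(b.reset_index(drop=True)):
                return False
        return True


def _empty_table(name: str) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in TABLE_SCHEMAS[name]})


def _iso_dates(rng: np.random.Generator, n: int, cfg: SimConfig) -> np.ndarray:
    start, end = cfg.date_range
    span = (end - start).days + 1
    offs = rng.integers(0, span, size=n)
    return np.array([(start + timedelta(days=int(d))).isoformat() for d in offs])


def _texts(rng: np.random.Generator, vocab: np.ndarray, n: int,
           lo: int = 1, hi: int = 3) -> np.ndarray:
    lengths = rng.integers(lo, hi + 1, size=n)
    words = rng.choice(vocab, size=int(lengths.sum()))
    out = np.empty(n, dtype=object)
    pos = 0
    for i, L in enumerate(lengths):
        out[i] = " ".join(words[pos:pos + L])
        pos += L
    return out


def _background_pools(cfg: SimConfig, vocab: np.ndarray):
    """Background sampling pools with all planted values excluded, so a
    planted feature's marginal rate and log-odds match the liability model
    instead of being diluted by chance background occurrences."""
    icd9_excl = {s.value.upper() for s in cfg.signal_spec
                 if s.kind.endswith("_icd9")}
    atc_excl = {s.value.upper() for s in cfg.signal_spec
                if s.kind == "medication_atc"}
    word_excl = {s.value.lower() for s in cfg.signal_spec
                 if s.kind.endswith("_word")}
    icd9 = np.array([c for c in _ICD9_CODES if c[:3].upper() not in icd9_excl])
    atc = np.array([c for c in _ATC_CODES if c[:3].upper() not in atc_excl])
    voc = np.array([w for w in vocab if w not in word_excl], dtype=object)
    return icd9, atc, voc


def _background_rows(rng: np.random.Generator, cfg: SimConfig, table: str,
                     patient_ids: np.ndarray, vocab: np.ndarray) -> pd.DataFrame:
    """Noise records for one satellite table, vectorized across patients."""
    icd9_pool, atc_pool, vocab = _background_pools(cfg, vocab)
    rate = cfg.rates.get(table, 0.0)
    if table == "encounter":
        counts = 1 + rng.poisson(max(rate - 1.0, 0.0), size=len(patient_ids))
    else:
        counts = rng.poisson(rate, size=len(patient_ids))
    pids = np.repeat(patient_ids, counts)
    m = len(pids)
    if m == 0:
        return _empty_table(table)
    dates = _iso_dates(rng, m, cfg)
    if table == "billing" or table == "encounter_diagnosis":
        return pd.DataFrame({
            "patient_id": pids,
            "date": dates,
            "icd9_code": rng.choice(icd9_pool, size=m),
            "diagnosis_text": _texts(rng, vocab, m),
        })
    if table == "encounter":
        return pd.DataFrame({
            "patient_id": pids,
            "date": dates,
            "encounter_reason_text": _texts(rng, vocab, m),
        })
    if table == "medication":
        drugs = rng.choice(np.array(_DRUG_NAMES), size=m)
        strengths = rng.choice(np.array(_DRUG_STRENGTHS), size=m)
        forms = rng.choice(np.array(_DRUG_FORMS), size=m)
        names = np.array([f"{d} {s} mg {f}" for d, s, f in zip(drugs, strengths, forms)],
                         dtype=object)
        return pd.DataFrame({
            "patient_id": pids,
            "date": dates,
            "atc_code": rng.choice(atc_pool, size=m),
            "medication_name_text": names,
        })
    if table == "lab":
        analytes = rng.choice(np.array(sorted(_LAB_ANALYTES)), size=m)
        mu = np.array([_LAB_ANALYTES[a][0] for a in analytes])
        sd = np.array([_LAB_ANALYTES[a][1] for a in analytes])
        units = np.array([_LAB_ANALYTES[a][2] for a in analytes], dtype=object)
        vals = np.round(np.exp(rng.normal(mu, sd)), 2)
        return pd.DataFrame({
            "patient_id": pids,
            "date": dates,
            "analyte_name": analytes,
            "value": vals,
            "unit": units,
        })
    if table == "exam":
        measures = rng.choice(np.array(sorted(_EXAM_MEASURES)), size=m)
        mu = np.array([_EXAM_MEASURES[x][0] for x in measures])
        sd = np.array([_EXAM_MEASURES[x][1] for x in measures])
        vals = np.round(np.maximum(rng.normal(mu, sd), 1.0), 1)
        return pd.DataFrame({
            "patient_id": pids,
            "date": dates,
            "measure_name": measures,
            "value": vals,
        })
    if table == "referral":
        targets = rng.choice(np.array(_REFERRAL_TARGETS, dtype=object), size=m)
        texts = np.array([f"referral to {t}" for t in targets], dtype=object)
        return pd.DataFrame({"patient_id": pids, "date": dates, "referral_text": texts})
    raise ValueError(f"unknown table {table!r}")


def _planted_rows(rng: np.random.Generator, cfg: SimConfig, sig: SignalFeature,
                  exposed_ids: np.ndarray, vocab: np.ndarray) -> pd.DataFrame:
    """One concrete EMR record per exposed patient for a planted feature."""
    m = len(exposed_ids)
    table = SIGNAL_KINDS[sig.kind]
    if m == 0:
        return _empty_table(table)
    dates = _iso_dates(rng, m, cfg)
    if sig.kind in ("billing_icd9", "encounter_diagnosis_icd9"):
        suffix = rng.choice(np.array(["", ".0", ".9"]), size=m)
        codes = np.array([sig.value + s for s in suffix], dtype=object)
        return pd.DataFrame({
            "patient_id": exposed_ids,
            "date": dates,
            "icd9_code": codes,
            "diagnosis_text": _texts(rng, vocab, m),
        })
    if sig.kind == "medication_atc":
        sub = rng.choice(np.array(["AA01", "CA01", "BA02", "DB04"]), size=m)
        codes = np.array([sig.value + s for s in sub], dtype=object)
        drugs = rng.choice(np.array(_DRUG_NAMES), size=m)
        names = np.array([f"{d} {rng.choice(_DRUG_STRENGTHS)} mg tablet" for d in drugs],
                         dtype=object)
        return pd.DataFrame({
            "patient_id": exposed_ids,
            "date": dates,
            "atc_code": codes,
            "medication_name_text": names,
        })
    if sig.kind == "medication_word":
        names = np.array([f"{sig.value} {w}" for w in rng.choice(vocab, size=m)],
                         dtype=object)
        return pd.DataFrame({
            "patient_id": exposed_ids,
            "date": dates,
            "atc_code": rng.choice(np.array(_ATC_CODES), size=m),
            "medication_name_text": names,
        })
    if sig.kind == "encounter_word":
        texts = np.array([f"{w} {sig.value}" for w in rng.choice(vocab, size=m)],
                         dtype=object)
        return pd.DataFrame({
            "patient_id": exposed_ids,
            "date": dates,
            "encounter_reason_text": texts,
        })
    if sig.kind == "billing_word":
        texts = np.array([f"{w} {sig.value}" for w in rng.choice(vocab, size=m)],
                         dtype=object)
        return pd.DataFrame({
            "patient_id": exposed_ids,
            "date": dates,
            "icd9_code": rng.choice(np.array(_ICD9_CODES), size=m),
            "diagnosis_text": texts,
        })
    raise ValueError(sig.kind)


def generate_cohort(config: SimConfig) -> tuple[EmrTables, list[CfsAssessment]]:
    """Generate one seeded cohort: EMR tables plus per-patient CFS assessments.

    All patients are eligible by construction: age >= 65 at the end of the
    date range and at least one encounter inside the window.  The frail
    fraction (CFS >= 5) is centred on ``config.target_prevalence`` by solving
    for the liability intercept on the realized exposures.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    width = max(4, len(str(n)))
    patient_ids = np.array([f"P{i + 1:0{width}d}" for i in range(n)], dtype=object)
    physician_ids = np.array(
        [f"D{i // cfg.patients_per_physician + 1:03d}" for i in range(n)], dtype=object
    )
    vocab = np.array(_WORDS[: cfg.vocab_size], dtype=object)

    end = cfg.date_range[1]
    ages = rng.integers(65, 96, size=n)
    birth_year = end.year - ages
    sex = rng.choice(np.array(["M", "F"]), size=n)

    # exposures and latent liability
    k = len(cfg.signal_spec)
    exposures = np.zeros((n, k), dtype=int)
    for j, sig in enumerate(cfg.signal_spec):
        exposures[:, j] = rng.random(n) < sig.base_rate
    weights = np.array([s.log_odds for s in cfg.signal_spec])
    eta = exposures @ weights if k else np.zeros(n)
    if cfg.physician_sd > 0:
        u = rng.normal(0.0, cfg.physician_sd, size=cfg.n_physicians)
        eta = eta + u[np.arange(n) // cfg.patients_per_physician]

    def mean_prev(b0: float) -> float:
        return float(np.mean(expit(b0 + eta))) - cfg.target_prevalence

    b0 = brentq(mean_prev, -30.0, 30.0)
    liability = b0 + eta + rng.logistic(size=n)
    cfs = 1 + np.sum(liability[:, None] > np.array(_CFS_THRESHOLDS)[None, :], axis=1)

    assessments = [
        CfsAssessment(pid, doc, int(s))
        for pid, doc, s in zip(patient_ids, physician_ids, cfs)
    ]

    tables: dict[str, pd.DataFrame] = {}
    tables["patient"] = pd.DataFrame({
        "patient_id": patient_ids,
        "sex": sex,
        "birth_year": birth_year.astype(int),
    })
    for name in ("billing", "encounter", "encounter_diagnosis", "exam",
                 "lab", "medication", "referral"):
        tables[name] = _background_rows(rng, cfg, name, patient_ids, vocab)

    # planted records appended to their tables
    for j, sig in enumerate(cfg.signal_spec):
        exposed = patient_ids[exposures[:, j] == 1]
        rows = _planted_rows(rng, cfg, sig, exposed, vocab)
        tname = SIGNAL_KINDS[sig.kind]
        tables[tname] = pd.concat([tables[tname], rows], ignore_index=True)

    # risk factors: each patient reports a random subset of the three factors
    rf_rows = []
    for factor, statuses in sorted(_RISK_FACTORS.items()):
        has = rng.random(n) < 0.5
        status = rng.choice(np.array(statuses), size=n)
        rf_rows.append(pd.DataFrame({
            "patient_id": patient_ids[has],
            "factor_name": factor,
            "status": status[has],
        }))
    tables["risk_factor"] = pd.concat(rf_rows, ignore_index=True)

    dc_rows = []
    for cond in DISEASE_CONDITIONS:
        has = rng.random(n) < 0.08
        dc_rows.append(pd.DataFrame({"patient_id": patient_ids[has], "condition": cond}))
    tables["disease_case"] = pd.concat(dc_rows, ignore_index=True)

    # deterministic ordering
    for name, df in tables.items():
        cols = TABLE_SCHEMAS[name]
        if len(df):
            df = df[cols].sort_values(cols, kind="mergesort").reset_index(drop=True)
        else:
            df = _empty_table(name)
        tables[name] = df

    return EmrTables(**tables), assessments


def write_tables(tables: EmrTables, directory: str | Path) -> list[Path]:
    """Write one CSV per table (header row, ISO-8601 dates); returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in tables.as_dict().items():
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False)
        paths.append(path)
    return paths


_DTYPES = {"birth_year": "int64", "value": "float64"}


def read_tables(directory: str | Path) -> EmrTables:
    """Read the table bundle back; errors name any missing table or column."""
    directory = Path(directory)
    out = {}
    for name, cols in TABLE_SCHEMAS.items():
        path = directory / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing table file for {name!r}: {path}")
        df = pd.read_csv(path, dtype=object, keep_default_na=False)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"table {name!r} is missing column(s) {missing}")
        unknown = [c for c in df.columns if c not in cols]
        if unknown:
            raise ValueError(f"table {name!r} has unknown column(s) {unknown}")
        for col, dt in _DTYPES.items():
            if col in df.columns and len(df):
                df[col] = df[col].astype(dt)
        out[name] = df if len(df) else _empty_table(name)
    return EmrTables(**out)


def write_assessments(assessments: list[CfsAssessment], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([dataclasses.asdict(a) for a in assessments]).to_csv(path, index=False)
    return path


def read_assessments(path: str | Path) -> list[CfsAssessment]:
    df = pd.read_csv(path, dtype={"patient_id": str, "physician_id": str})
    return [
        CfsAssessment(r.patient_id, r.physician_id, int(r.cfs_score))
        for r in df.itertuples()
    ]
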