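"""EMR-to-feature-matrix transformation for the frailty case definition.

Every feature family follows the published extraction rules:

* diagnosis and billing ICD-9 codes truncated to their first 3 characters
  (disease category level), one presence indicator per truncated code;
* free-text fields (billing diagnosis text, encounter reason,
  encounter-diagnosis text, medication name) turned into a unigram
  term-document matrix: lowercase tokens split on non-alphanumerics, numeric
  tokens kept, no stop-word removal;
* ATC medication codes truncated to level 2 (therapeutic subgroup, e.g. C03
  = diuretics), one indicator per subgroup;
* lab values and biometrics binarized to low / normal / high against fixed
  clinical cut-offs (range endpoints inclusive in "normal"); waist is
  dichotomized large/small at a sex-specific cut-off;
* per-table aggregates over the two years preceding each patient's latest
  encounter: unique-record counts per year, absolute and relative change
  between years (numeric), and a "poly" category of the two-year total at
  cut-offs 5 and 10;
* disease-case indicators, referral indicators, risk-factor statuses, sex,
  and numeric age.

Missing data encodes as 0.  Binary features observed in 5 or fewer patients
are dropped (sparsity filter); numeric features (age, change features) are
exempt.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import LabelSet
from .simulate import EmrTables

__all__ = [
    "CutoffTable",
    "DEFAULT_CUTOFFS",
    "FeatureMatrix",
    "AggregateSummary",
    "binarize_value",
    "truncate_icd9",
    "truncate_atc",
    "tokenize_unigrams",
    "count_category",
    "aggregate_features",
    "build_feature_matrix",
]

_TOKEN_SPLIT = re.compile(r"[^a-z0-9]+")

COUNT_CATEGORIES = ("less than 5", "between 5 and 10", "greater than 10")


@dataclass(frozen=True)
class CutoffTable:
    """Low/high cut-offs per analyte: value < low -> "low", value > high ->
    "high", endpoints inclusive in "normal". ``units`` is informational."""

    cutoffs: dict[str, tuple[float, float]]
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for analyte, (lo, hi) in self.cutoffs.items():
            if not lo < hi:
                raise ValueError(f"cutoffs for {analyte!r} must satisfy low < high")

    @property
    def analytes(self) -> list[str]:
        return sorted(self.cutoffs)


#: standard clinical cut-offs for the lab and biometric values
DEFAULT_CUTOFFS = CutoffTable(
    cutoffs={
        "creatinine": (53.0, 106.0),
        "glucose_fasting": (3.9, 6.1),
        "hemoglobin": (135.0, 180.0),
        "tsh": (0.5, 5.0),
        "bmi": (22.0, 30.0),
        "systolic_bp": (90.0, 140.0),
    },
    units={
        "creatinine": "umol/L",
        "glucose_fasting": "mmol/L",
        "hemoglobin": "g/L",
        "tsh": "mU/L",
        "bmi": "kg/m2",
        "systolic_bp": "mmHg",
    },
)

#: sex-specific waist-circumference cut-off (cm) for the "large waist" flag
DEFAULT_WAIST_CUTOFFS = {"M": 102.0, "F": 88.0}


def binarize_value(value: float, analyte: str, cutoffs: CutoffTable = DEFAULT_CUTOFFS) -> str:
    """Categorize a positive lab/biometric value as low / normal / high."""
    if analyte not in cutoffs.cutoffs:
        raise KeyError(
            f"unknown analyte {analyte!r}; known analytes: {cutoffs.analytes}"
        )
    if not value > 0:
        raise ValueError(f"value must be positive, got {value}")
    lo, hi = cutoffs.cutoffs[analyte]
    if value < lo:
        return "low"
    if value > hi:
        return "high"
    return "normal"


def truncate_icd9(code: str) -> str:
    """First 3 characters of an ICD-9 code (disease category), uppercased."""
    s = str(code).strip().upper()
    if not s:
        raise ValueError("empty ICD-9 code")
    return s[:3]


def truncate_atc(code: str) -> str:
    """ATC code reduced to level 2 (therapeutic subgroup; 3 characters)."""
    s = str(code).strip().upper()
    if len(s) < 3:
        raise ValueError(f"ATC code {code!r} shorter than 3 characters")
    return s[:3]


def tokenize_unigrams(text: str) -> set[str]:
    """Lowercase unigrams split on non-alphanumerics; numeric tokens kept."""
    if text is None:
        return set()
    return {t for t in _TOKEN_SPLIT.split(str(text).lower()) if t}


def count_category(n: int) -> str:
    """Record-count category at cut-offs 5 and 10 (both inclusive in the middle)."""
    if n < 0:
        raise ValueError(f"count must be non-negative, got {n}")
    if n < 5:
        return COUNT_CATEGORIES[0]
    if n <= 10:
        return COUNT_CATEGORIES[1]
    return COUNT_CATEGORIES[2]


@dataclass(frozen=True)
class AggregateSummary:
    """Unique-record aggregates over the two years before the reference date."""

    count_year1: int
    count_year2: int
    absolute_change: int
    relative_change: float
    poly_category: str


def aggregate_features(dates: pd.Series, values: pd.Series,
                       reference_date: pd.Timestamp | None) -> AggregateSummary:
    """Aggregate one patient's records in one table.

    Year 1 is the 12 months ending at the reference date, year 2 the 12
    months before that; counts are of unique record values. The relative
    change divides by max(count_year2, 1).  A missing reference date yields
    all-zero aggregates (missing-as-zero rule).
    """
    if reference_date is None or pd.isna(reference_date):
        return AggregateSummary(0, 0, 0, 0.0, count_category(0))
    ref = pd.Timestamp(reference_date)
    d = pd.to_datetime(dates)
    y1 = (d > ref - pd.DateOffset(months=12)) & (d <= ref)
    y2 = (d > ref - pd.DateOffset(months=24)) & (d <= ref - pd.DateOffset(months=12))
    c1 = values[y1].nunique()
    c2 = values[y2].nunique()
    total = values[y1 | y2].nunique()
    abs_change = c1 - c2
    rel_change = abs_change / max(c2, 1)
    return AggregateSummary(c1, c2, abs_change, rel_change, count_category(total))


@dataclass
class FeatureMatrix:
    """Patients x features with provenance metadata.

    ``X`` holds binary indicator columns plus the numeric exceptions (age and
    the change features).  ``meta`` has one row per retained feature: name,
    family, source table, and support (number of patients with a nonzero
    value).
    """

    X: pd.DataFrame
    meta: pd.DataFrame
    n_features_pre: int
    n_features_post: int

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def to_dir(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        long = self.X.stack()
        long = long[long != 0]
        trip = long.reset_index()
        trip.columns = ["patient_id", "feature_name", "value"]
        trip.to_csv(directory / "matrix.csv", index=False)
        self.meta.to_csv(directory / "features.csv", index=False)
        pd.DataFrame({"patient_id": self.X.index}).to_csv(
            directory / "patients.csv", index=False
        )

    @classmethod
    def from_dir(cls, directory: str | Path) -> "FeatureMatrix":
        directory = Path(directory)
        trip = pd.read_csv(directory / "matrix.csv",
                           dtype={"patient_id": str, "feature_name": str})
        meta = pd.read_csv(directory / "features.csv")
        patients = pd.read_csv(directory / "patients.csv", dtype=str)["patient_id"]
        X = trip.pivot_table(index="patient_id", columns="feature_name",
                             values="value", fill_value=0.0, aggfunc="first")
        X = X.reindex(index=patients, columns=meta["name"], fill_value=0.0)
        X.index.name = "patient_id"
        X.columns.name = None
        return cls(X=X.astype(float), meta=meta,
                   n_features_pre=len(meta), n_features_post=len(meta))


def _indicator_pairs(pids: pd.Series, names: pd.Series, family: str,
                     source: str) -> pd.DataFrame:
    df = pd.DataFrame({"patient_id": pids.to_numpy(), "name": names.to_numpy()})
    df = df.dropna().drop_duplicates()
    df["family"] = family
    df["source"] = source
    return df


def _slug(text: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", str(text).lower()).strip("_")


def _token_pairs(table: pd.DataFrame, text_col: str, prefix: str,
                 source: str) -> pd.DataFrame:
    if table.empty:
        return pd.DataFrame(columns=["patient_id", "name", "family", "source"])
    s = table[text_col].fillna("").astype(str).str.lower()
    tokens = s.str.split(_TOKEN_SPLIT)
    df = pd.DataFrame({"patient_id": table["patient_id"].to_numpy(),
                       "token": tokens.to_numpy()})
    df = df.explode("token")
    df = df[df["token"].astype(bool)]
    df["name"] = prefix + df["token"].astype(str)
    return _indicator_pairs(df["patient_id"], df["name"], "text_unigram", source)


def build_feature_matrix(
    tables: EmrTables,
    labels: LabelSet,
    cutoffs: CutoffTable = DEFAULT_CUTOFFS,
    min_support: int = 6,
    as_of: pd.Timestamp | None = None,
    waist_cutoffs: dict[str, float] | None = None,
) -> FeatureMatrix:
    """Assemble the full binary feature matrix for the labelled patients.

    ``as_of`` anchors age and serves as the fallback reference date for
    patients without encounters; it defaults to the latest encounter date in
    the cohort.  Binary features supported by fewer than ``min_support``
    patients are dropped.
    """
    patients = pd.Index(labels.patient_ids, name="patient_id")
    if len(patients) == 0:
        raise ValueError("no labelled patients")
    waist_cutoffs = waist_cutoffs or DEFAULT_WAIST_CUTOFFS

    enc = tables.encounter
    if as_of is None:
        if enc.empty:
            raise ValueError("cannot infer as_of: encounter table is empty")
        as_of = pd.to_datetime(enc["date"]).max()
    as_of = pd.Timestamp(as_of)

    # per-patient reference date: latest encounter, fallback as_of
    if enc.empty:
        ref_dates = pd.Series(as_of, index=patients)
    else:
        latest = pd.to_datetime(enc["date"]).groupby(enc["patient_id"].to_numpy()).max()
        ref_dates = latest.reindex(patients).fillna(as_of)

    pairs: list[pd.DataFrame] = []

    # truncated ICD-9 indicators
    for tbl, prefix, source in ((tables.billing, "bil_icd9_", "billing"),
                                (tables.encounter_diagnosis, "ed_icd9_",
                                 "encounter_diagnosis")):
        if not tbl.empty:
            codes = tbl["icd9_code"].astype(str).map(truncate_icd9)
            pairs.append(_indicator_pairs(tbl["patient_id"], prefix + codes,
                                          "icd9_truncated", source))

    # unigram term-document indicators
    pairs.append(_token_pairs(tables.billing, "diagnosis_text", "bil_word_", "billing"))
    pairs.append(_token_pairs(tables.encounter, "encounter_reason_text",
                              "enc_word_", "encounter"))
    pairs.append(_token_pairs(tables.encounter_diagnosis, "diagnosis_text",
                              "ed_word_", "encounter_diagnosis"))
    pairs.append(_token_pairs(tables.medication, "medication_name_text",
                              "med_word_", "medication"))

    # level-2 ATC indicators
    med = tables.medication
    if not med.empty:
        atc = med["atc_code"].astype(str).map(truncate_atc)
        pairs.append(_indicator_pairs(med["patient_id"], "med_atc_" + atc,
                                      "atc_truncated", "medication"))

    # lab categories
    lab = tables.lab
    if not lab.empty:
        cats = [
            binarize_value(float(v), a, cutoffs)
            for v, a in zip(lab["value"], lab["analyte_name"])
        ]
        names = "lab_" + lab["analyte_name"].astype(str) + "_" + pd.Series(
            cats, index=lab.index
        )
        pairs.append(_indicator_pairs(lab["patient_id"], names, "lab_category", "lab"))

    # exam categories (waist dichotomized by sex-specific cut-off)
    exam = tables.exam
    if not exam.empty:
        sex_map = tables.patient.set_index("patient_id")["sex"]
        waist = exam[exam["measure_name"] == "waist"]
        if not waist.empty:
            sex = waist["patient_id"].map(sex_map)
            cut = sex.map(waist_cutoffs).astype(float)
            wnames = np.where(waist["value"].astype(float) > cut,
                              "exam_waist_large", "exam_waist_small")
            pairs.append(_indicator_pairs(waist["patient_id"],
                                          pd.Series(wnames, index=waist.index),
                                          "exam_category", "exam"))
        other = exam[exam["measure_name"] != "waist"]
        if not other.empty:
            cats = [
                binarize_value(float(v), m, cutoffs)
                for v, m in zip(other["value"], other["measure_name"])
            ]
            names = "exam_" + other["measure_name"].astype(str) + "_" + pd.Series(
                cats, index=other.index
            )
            pairs.append(_indicator_pairs(other["patient_id"], names,
                                          "exam_category", "exam"))

    # disease-case, referral, risk-factor indicators
    dc = tables.disease_case
    if not dc.empty:
        names = "dc_" + dc["condition"].map(_slug)
        pairs.append(_indicator_pairs(dc["patient_id"], names, "disease_case",
                                      "disease_case"))
    ref_tbl = tables.referral
    if not ref_tbl.empty:
        names = "ref_" + ref_tbl["referral_text"].map(_slug)
        pairs.append(_indicator_pairs(ref_tbl["patient_id"], names, "referral",
                                      "referral"))
    rf = tables.risk_factor
    if not rf.empty:
        names = ("risk_" + rf["factor_name"].map(_slug) + "_"
                 + rf["status"].map(_slug))
        pairs.append(_indicator_pairs(rf["patient_id"], names, "risk_factor",
                                      "risk_factor"))

    # sex indicator
    pat = tables.patient
    males = pat.loc[pat["sex"] == "M", "patient_id"]
    pairs.append(_indicator_pairs(males, pd.Series("sex_male", index=males.index),
                                  "sex", "patient"))

    # aggregate count categories (binary) for billing / encounter diagnosis /
    # medication; pairs appended below, numeric changes collected separately
    numeric_cols: dict[str, pd.Series] = {}
    agg_specs = (
        (tables.billing, "icd9_code", "bil", "billing"),
        (tables.encounter_diagnosis, "icd9_code", "ed", "encounter_diagnosis"),
        (tables.medication, "atc_code", "med", "medication"),
    )
    for tbl, value_col, pfx, source in agg_specs:
        zero = pd.Series(0.0, index=patients)
        if tbl.empty:
            c1 = c2 = total = zero
        else:
            sub = tbl[tbl["patient_id"].isin(patients)]
            d = pd.to_datetime(sub["date"])
            ref = sub["patient_id"].map(ref_dates)
            y1 = (d > ref - pd.DateOffset(months=12)) & (d <= ref)
            y2 = ((d > ref - pd.DateOffset(months=24))
                  & (d <= ref - pd.DateOffset(months=12)))

            def _nunique(mask: pd.Series) -> pd.Series:
                s = sub[mask]
                if s.empty:
                    return zero
                g = s.groupby("patient_id")[value_col].nunique()
                return g.reindex(patients).fillna(0).astype(float)

            c1, c2, total = _nunique(y1), _nunique(y2), _nunique(y1 | y2)
        abs_ch = c1 - c2
        rel_ch = abs_ch / np.maximum(c2, 1.0)
        cats = total.map(lambda t: count_category(int(t)))
        cat_df = pd.DataFrame({
            "patient_id": patients,
            "name": [f"{pfx}_poly_{_slug(c)}" for c in cats],
        })
        pairs.append(_indicator_pairs(cat_df["patient_id"], cat_df["name"],
                                      "aggregate_count_category", source))
        numeric_cols[f"{pfx}_records_change_abs"] = abs_ch
        numeric_cols[f"{pfx}_records_change_rel"] = rel_ch

    # assemble binary matrix
    all_pairs = pd.concat(pairs, ignore_index=True)
    all_pairs = all_pairs[all_pairs["patient_id"].isin(patients)]
    all_pairs = all_pairs.drop_duplicates(subset=["patient_id", "name"])
    fam_map = all_pairs.drop_duplicates("name").set_index("name")[["family", "source"]]

    wide = pd.crosstab(all_pairs["patient_id"], all_pairs["name"])
    wide = wide.reindex(index=patients, fill_value=0).astype(int)
    wide.columns.name = None

    n_pre = wide.shape[1] + len(numeric_cols) + 1  # +1 for age

    support = wide.sum(axis=0)
    keep = support[support >= min_support].index
    wide = wide[keep]

    # age (numeric, exempt from the sparsity filter)
    age = (as_of.year - pat.set_index("patient_id")["birth_year"]).reindex(patients)
    age = age.astype(float)

    meta_rows = [
        {"name": c, "family": fam_map.loc[c, "family"],
         "source": fam_map.loc[c, "source"], "support": int(support[c])}
        for c in wide.columns
    ]
    num_frame = {}
    for cname, col in numeric_cols.items():
        src = {"bil": "billing", "ed": "encounter_diagnosis", "med": "medication"}[
            cname.split("_")[0]
        ]
        num_frame[cname] = col.astype(float)
        meta_rows.append({"name": cname, "family": "change_feature", "source": src,
                          "support": int((col != 0).sum())})
    num_frame["age"] = age
    meta_rows.append({"name": "age", "family": "age", "source": "patient",
                      "support": int(len(patients))})

    X = pd.concat([wide.astype(float), pd.DataFrame(num_frame, index=patients)], axis=1)
    meta = pd.DataFrame(meta_rows)

    # stable ordering: family, then name
    meta = meta.sort_values(["family", "name"], kind="mergesort").reset_index(drop=True)
    X = X[meta["name"].tolist()]

    return FeatureMatrix(X=X, meta=meta, n_features_pre=int(n_pre),
                         n_features_post=int(X.shape[1]))
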