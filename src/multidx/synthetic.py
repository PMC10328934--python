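"""Synthetic longitudinal EHR generator with a known logistic ground truth.

Real outpatient EHR streams of the kind this package models are not publicly
available, so every downstream stage (cohort selection, label grouping,
feature aggregation, modelling, evaluation, interpretation) is developed and
tested against data from this generator. The generator emits the same four
event tables the cohort builder consumes — patients, encounters, diagnoses,
labs — and, crucially, returns the generative mechanism itself
(:class:`GroundTruth`) so that recovery tests can compare fitted models
against the truth.

The mechanism: each patient accumulates encounters over a multi-year span;
at each encounter, every code in the alphabet is drawn Bernoulli from a
logistic model whose covariates are exactly the windowed history features the
feature builder produces (demographics, presence of each code in the past
diagnosis window, most-recent lab values in the past lab window). Chronic
codes carry a large positive self-weight, so once acquired they recur at
subsequent encounters with high probability; acute codes have a weak
self-weight; "null" codes have all-zero weights and depend on nothing.
A subset of numeric labs is emitted with deliberately inconsistent units and
name variants, and some labs are categorical, to exercise harmonization.
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GroundTruth",
    "EventTables",
    "generate",
    "true_risk",
    "harmonization_tables",
    "cci_table",
    "DEFAULT_ALPHABET",
]

#: Letters whose codes are symptoms / external causes / health-status factors;
#: they are never prediction targets downstream.
EXCLUDED_LETTERS = frozenset("RUVWXYZ")

#: Default code alphabet: twenty predictable three-character codes spanning
#: many chapters, plus two excluded-letter codes (symptom / status codes)
#: that downstream stages must filter out of the label space.
DEFAULT_ALPHABET = (
    "A09", "A41", "B20", "C34", "D50", "E11", "E78", "F31", "G40", "H25",
    "I10", "I25", "J06", "J44", "K21", "L40", "M54", "N18", "S72", "T78",
    "R07", "Z79",
)

_STUDY_START = np.datetime64("2008-01-01")
_SECONDS = None  # no wall-clock anywhere; determinism is from the seed only


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults describe the standing study conditions: a few thousand patients
    followed for most of a decade, a median of about five encounters per
    patient, twenty candidate disease codes of which a quarter are pure
    noise, and half chronic.
    """

    n_patients: int = 2000
    years_span: float = 9.0
    mean_encounters_per_patient: float = 7.0
    label_alphabet: tuple[str, ...] = DEFAULT_ALPHABET
    n_labs: int = 10
    chronic_fraction: float = 0.5
    signal_strength: float = 1.0
    null_label_fraction: float = 0.25
    seed: int = 0
    #: diagnosis / lab look-back windows (days) used by the true model
    diag_window_days: int = 3650
    lab_window_days: int = 365
    #: additive shift applied to every label's baseline log-odds — a control
    #: knob for prevalence-monotonicity checks
    baseline_shift: float = 0.0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError(f"n_patients must be >= 1, got {self.n_patients}")
        if self.years_span <= 0:
            raise ValueError(f"years_span must be > 0, got {self.years_span}")
        if self.mean_encounters_per_patient <= 0:
            raise ValueError("mean_encounters_per_patient must be > 0")
        if not 0.0 <= self.chronic_fraction <= 1.0:
            raise ValueError("chronic_fraction must be in [0, 1]")
        if not 0.0 <= self.null_label_fraction <= 1.0:
            raise ValueError("null_label_fraction must be in [0, 1]")
        if self.chronic_fraction + self.null_label_fraction > 1.0:
            raise ValueError("chronic_fraction + null_label_fraction must be <= 1")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")
        if self.n_labs < 1:
            raise ValueError("n_labs must be >= 1")
        letters = {c[0] for c in self.label_alphabet}
        if len(self.label_alphabet) < 2 or len(letters - EXCLUDED_LETTERS) < 1:
            raise ValueError("label_alphabet must contain predictable codes")


@dataclass
class EventTables:
    """The four raw event tables: the universal input of the pipeline."""

    patients: pd.DataFrame    # patient_id, birth_date, sex
    encounters: pd.DataFrame  # encounter_id, patient_id, date, type, status
    diagnoses: pd.DataFrame   # encounter_id, patient_id, date, icd10_code
    labs: pd.DataFrame        # patient_id, date, lab_name, raw_value, unit

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("patients", "encounters", "diagnoses", "labs"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)

    @classmethod
    def read(cls, in_dir: str | Path) -> "EventTables":
        p = Path(in_dir)
        kw = dict(dtype=str, keep_default_na=False)
        t = cls(
            patients=pd.read_csv(p / "patients.csv", **kw),
            encounters=pd.read_csv(p / "encounters.csv", **kw),
            diagnoses=pd.read_csv(p / "diagnoses.csv", **kw),
            labs=pd.read_csv(p / "labs.csv", **kw),
        )
        for df, col in ((t.patients, "birth_date"), (t.encounters, "date"),
                        (t.diagnoses, "date"), (t.labs, "date")):
            df[col] = pd.to_datetime(df[col])
        return t

    def serialize_bytes(self) -> bytes:
        """Canonical byte serialization of all four tables (determinism checks)."""
        buf = io.StringIO()
        for name in ("patients", "encounters", "diagnoses", "labs"):
            getattr(self, name).to_csv(buf, index=False)
        return buf.getvalue().encode()


@dataclass
class GroundTruth:
    """The generative mechanism: per-code logistic weights over history features.

    ``weights`` rows are alphabet codes, columns are feature names matching
    the feature builder's schema (``demo:age``, ``diag:I25``,
    ``lab_value:LAB03`` ...). Null codes have all-zero rows.
    """

    feature_names: list[str]
    weights: pd.DataFrame
    baselines: pd.Series
    chronic: pd.Series
    is_null: pd.Series
    lab_registry: pd.DataFrame
    diag_window_days: int
    lab_window_days: int

    def __post_init__(self) -> None:
        w = self.weights.to_numpy(dtype=float)
        if not np.isfinite(w).all():
            raise ValueError("ground-truth weights must be finite")
        null_rows = w[self.is_null.to_numpy(bool)]
        if null_rows.size and np.abs(null_rows).max() > 0:
            raise ValueError("null labels must have all-zero weight vectors")

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": self.feature_names,
                "weights": {c: self.weights.loc[c].to_dict() for c in self.weights.index},
                "baselines": self.baselines.to_dict(),
                "chronic": {k: bool(v) for k, v in self.chronic.items()},
                "is_null": {k: bool(v) for k, v in self.is_null.items()},
                "lab_registry": self.lab_registry.to_dict(orient="records"),
                "diag_window_days": self.diag_window_days,
                "lab_window_days": self.lab_window_days,
            },
            indent=1,
            sort_keys=True,
        )


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def true_risk(truth: GroundTruth, features: np.ndarray, label: str) -> float:
    """Probability of ``label`` at an encounter with the given history features.

    ``features`` must align with ``truth.feature_names``.
    """
    f = np.asarray(features, dtype=float)
    if f.shape != (len(truth.feature_names),):
        raise ValueError(
            f"feature vector has shape {f.shape}, expected ({len(truth.feature_names)},)"
        )
    z = float(truth.baselines[label]) + float(truth.weights.loc[label].to_numpy() @ f)
    return float(_sigmoid(z))


def _zero_truncated_negbinom(rng: np.random.Generator, mean: float, r: float,
                             size: int) -> np.ndarray:
    """Zero-truncated negative binomial counts with the given untruncated mean.

    Overdispersed (r ~ 1.2) so that with mean ~7 the median lands near 5,
    with a long right tail, mimicking real per-patient encounter counts.
    """
    p = r / (r + mean)
    out = rng.negative_binomial(r, p, size=size)
    while (mask := out == 0).any():
        out[mask] = rng.negative_binomial(r, p, size=int(mask.sum()))
    return out


_CANONICAL_UNITS = ("mg/dL", "mmol/L", "U/L", "g/dL", "ng/mL", "%")
_POS_STRINGS = ("Positive", "DETECTED", "Abnormal")
_NEG_STRINGS = ("Negative", "NOT DETECTED", "Normal")


def _build_truth(cfg: SimConfig, rng: np.random.Generator) -> GroundTruth:
    codes = list(cfg.label_alphabet)
    excluded = np.array([c[0].upper() in EXCLUDED_LETTERS for c in codes])
    predictable = [c for c, ex in zip(codes, excluded) if not ex]

    n_pred = len(predictable)
    n_chronic = int(round(cfg.chronic_fraction * n_pred))
    n_null = int(round(cfg.null_label_fraction * n_pred))
    perm = rng.permutation(n_pred)
    chronic_set = {predictable[i] for i in perm[:n_chronic]}
    # null codes drawn from the acute remainder: a chronic, persistent code
    # cannot be independent of history
    null_set = {predictable[i] for i in perm[n_chronic:n_chronic + n_null]}

    # lab registry
    lab_ids = [f"LAB{j:02d}" for j in range(cfg.n_labs)]
    n_numeric = max(1, int(round(0.8 * cfg.n_labs)))
    kinds = ["numeric"] * n_numeric + ["nonnumeric"] * (cfg.n_labs - n_numeric)
    mus = rng.uniform(40.0, 160.0, size=cfg.n_labs)
    sds = 0.15 * mus
    units = [
        _CANONICAL_UNITS[j % len(_CANONICAL_UNITS)] if kinds[j] == "numeric" else ""
        for j in range(cfg.n_labs)
    ]
    # first (up to) two numeric labs are emitted with mixed units and a name
    # variant on a random subset of events
    confused = [j < min(2, n_numeric) and kinds[j] == "numeric" for j in range(cfg.n_labs)]
    registry = pd.DataFrame(
        {
            "lab_id": lab_ids,
            "kind": kinds,
            "canonical_unit": units,
            "mu": mus,
            "sd": sds,
            "confused": confused,
            "confusion_factor": [10.0 if c else 1.0 for c in confused],
        }
    )

    feature_names = (
        ["demo:age", "demo:sex_M", "demo:sex_F", "demo:sex_Unknown"]
        + [f"diag:{c}" for c in codes]
        + [f"lab_presence:{lid}" for lid, k in zip(lab_ids, kinds) if k == "numeric"]
        + [f"lab_value:{lid}" for lid, k in zip(lab_ids, kinds) if k == "numeric"]
        + [f"lab_pos:{lid}" for lid, k in zip(lab_ids, kinds) if k == "nonnumeric"]
    )
    fidx = {name: i for i, name in enumerate(feature_names)}

    W = np.zeros((len(codes), len(feature_names)))
    baselines = np.empty(len(codes))
    s = cfg.signal_strength
    numeric_ids = [lid for lid, k in zip(lab_ids, kinds) if k == "numeric"]
    for i, code in enumerate(codes):
        if excluded[i]:
            # symptom/status codes: common, history-independent
            baselines[i] = np.log(0.15 / 0.85) + rng.normal(0, 0.2)
            continue
        if code in null_set:
            # history-independent control labels: moderately common, so
            # their null behaviour is measurable on held-out splits
            target_prev = np.exp(rng.uniform(np.log(0.05), np.log(0.12)))
            baselines[i] = np.log(target_prev / (1 - target_prev))
            continue
        target_prev = np.exp(rng.uniform(np.log(0.01), np.log(0.06)))
        baselines[i] = np.log(target_prev / (1 - target_prev))
        # self-weight: strong persistence for chronic codes, weak for acute
        W[i, fidx[f"diag:{code}"]] = s * (rng.uniform(2.5, 3.5) if code in chronic_set
                                          else rng.uniform(0.2, 0.6))
        # cross-dependence on three other codes, mostly risk-increasing
        others = [c for c in codes if c != code]
        for c in rng.choice(len(others), size=3, replace=False):
            sign = 1.0 if rng.random() < 0.8 else -1.0
            W[i, fidx[f"diag:{others[c]}"]] = s * sign * rng.uniform(0.4, 1.0)
        # one numeric lab influences the code through its standardized value
        j = int(rng.integers(len(numeric_ids)))
        lid = numeric_ids[j]
        mu_j, sd_j = mus[lab_ids.index(lid)], sds[lab_ids.index(lid)]
        w_z = s * (1.0 if rng.random() < 0.7 else -1.0) * rng.uniform(0.4, 0.9)
        # expressed on the raw canonical-unit scale the feature builder emits
        W[i, fidx[f"lab_value:{lid}"]] = w_z / sd_j
        W[i, fidx[f"lab_presence:{lid}"]] = s * 0.3 - w_z * mu_j / sd_j
        # mild age effect (per year of age)
        W[i, fidx["demo:age"]] = s * rng.uniform(0.0, 0.02)

    return GroundTruth(
        feature_names=feature_names,
        weights=pd.DataFrame(W, index=codes, columns=feature_names),
        baselines=pd.Series(baselines, index=codes),
        chronic=pd.Series([c in chronic_set for c in codes], index=codes),
        is_null=pd.Series([c in null_set for c in codes], index=codes),
        lab_registry=registry,
        diag_window_days=cfg.diag_window_days,
        lab_window_days=cfg.lab_window_days,
    )


def generate(cfg: SimConfig) -> tuple[EventTables, GroundTruth]:
    """Simulate the cohort defined by ``cfg``.

    Deterministic: identical configs (including seed) yield byte-identical
    tables. All randomness flows from one seeded generator; no global state.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    truth = _build_truth(cfg, rng)
    if cfg.baseline_shift:
        truth.baselines = truth.baselines + cfg.baseline_shift
    codes = list(cfg.label_alphabet)
    reg = truth.lab_registry
    n_labs = len(reg)
    numeric_mask = (reg["kind"] == "numeric").to_numpy()
    lab_ids = reg["lab_id"].tolist()

    span_days = int(cfg.years_span * 365.25)
    start_day = _STUDY_START.astype("datetime64[D]").astype(int)

    # ---- patients ----------------------------------------------------------
    pat_ids = [f"P{i:06d}" for i in range(cfg.n_patients)]
    sex = rng.choice(["M", "F", "Unknown"], size=cfg.n_patients, p=[0.44, 0.555, 0.005])
    age_at_start = rng.uniform(1.0, 85.0, size=cfg.n_patients)
    birth_days = (start_day - (age_at_start * 365.25)).astype(int)

    n_enc = _zero_truncated_negbinom(rng, cfg.mean_encounters_per_patient, 1.2,
                                     cfg.n_patients)

    # latent per-patient lab levels
    z_lat = rng.standard_normal((cfg.n_patients, n_labs))

    W = truth.weights.to_numpy()
    b = truth.baselines.to_numpy()
    fnames = truth.feature_names
    fidx = {n: i for i, n in enumerate(fnames)}
    n_feat = len(fnames)
    diag_offsets = np.array([fidx[f"diag:{c}"] for c in codes])
    num_pres = np.array([fidx[f"lab_presence:{lid}"]
                         for lid, m in zip(lab_ids, numeric_mask) if m], dtype=int)
    num_val = np.array([fidx[f"lab_value:{lid}"]
                        for lid, m in zip(lab_ids, numeric_mask) if m], dtype=int)
    numeric_idx = np.flatnonzero(numeric_mask)
    nonnum_idx = np.flatnonzero(~numeric_mask)
    nn_pos = np.array([fidx[f"lab_pos:{lab_ids[j]}"] for j in nonnum_idx], dtype=int)
    mus = reg["mu"].to_numpy()
    sds = reg["sd"].to_numpy()

    enc_rows: list[tuple] = []
    dx_rows: list[tuple] = []
    lab_rows: list[tuple] = []
    enc_counter = 0

    for p in range(cfg.n_patients):
        k = int(n_enc[p])
        days = np.sort(rng.choice(span_days, size=min(k, span_days), replace=False))
        abs_days = start_day + days

        # lab event stream, independent of the diagnosis process
        n_lab_ev = rng.poisson(1.2 * k)
        lab_days = start_day + np.sort(rng.integers(0, span_days, size=n_lab_ev))
        lab_which = rng.integers(0, n_labs, size=n_lab_ev)
        lab_vals = np.empty(n_lab_ev)
        lab_pos = np.zeros(n_lab_ev, dtype=bool)
        for e in range(n_lab_ev):
            j = lab_which[e]
            if numeric_mask[j]:
                lab_vals[e] = mus[j] + sds[j] * (0.8 * z_lat[p, j]
                                                 + 0.6 * rng.standard_normal())
            else:
                lab_vals[e] = np.nan
                lab_pos[e] = rng.random() < _sigmoid(z_lat[p, j])

        age0 = (abs_days - birth_days[p]) / 365.25
        sex_vec = {"M": (1, 0, 0), "F": (0, 1, 0)}.get(sex[p], (0, 0, 1))

        # encounter type/status mix: most are completed office visits
        u = rng.random(k)
        types = np.where(u < 0.90, "Office Visit", "Telephone")
        status = np.where(rng.random(k) < 0.94, "Completed", "Canceled")

        code_days: list[list[int]] = [[] for _ in codes]
        for t in range(k):
            d = int(abs_days[t])
            f = np.zeros(n_feat)
            f[0] = age0[t]
            f[1], f[2], f[3] = sex_vec
            lo = d - cfg.diag_window_days
            for ci, dlist in enumerate(code_days):
                if dlist and dlist[-1] < d and dlist[-1] >= lo:
                    f[diag_offsets[ci]] = 1.0
                elif dlist and any(lo <= dd < d for dd in dlist):
                    f[diag_offsets[ci]] = 1.0
            llo = d - cfg.lab_window_days
            in_win = (lab_days >= llo) & (lab_days < d)
            if in_win.any():
                for jj, j in enumerate(numeric_idx):
                    sel = in_win & (lab_which == j)
                    if sel.any():
                        ii = np.flatnonzero(sel)
                        last_day = lab_days[ii].max()
                        vals = lab_vals[ii[lab_days[ii] == last_day]]
                        f[num_pres[jj]] = 1.0
                        f[num_val[jj]] = vals.max()
                for jj, j in enumerate(nonnum_idx):
                    sel = in_win & (lab_which == j)
                    if sel.any() and lab_pos[sel].any():
                        f[nn_pos[jj]] = 1.0

            probs = _sigmoid(b + W @ f)
            ys = rng.random(len(codes)) < probs

            eid = f"E{enc_counter:08d}"
            enc_counter += 1
            date_str = str(np.datetime64(d, "D"))
            enc_rows.append((eid, pat_ids[p], date_str, types[t], status[t]))
            for ci in np.flatnonzero(ys):
                suffix = rng.integers(0, 2)
                dx_rows.append((eid, pat_ids[p], date_str, f"{codes[ci]}.{suffix}"))
                code_days[ci].append(d)

        # emit lab table rows, with unit confusion on affected labs
        for e in range(n_lab_ev):
            j = lab_which[e]
            lid = lab_ids[j]
            date_str = str(np.datetime64(int(lab_days[e]), "D"))
            if numeric_mask[j]:
                name, unit, val = lid, reg["canonical_unit"].iloc[j], lab_vals[e]
                if reg["confused"].iloc[j] and rng.random() < 0.25:
                    val = val * reg["confusion_factor"].iloc[j]
                    name, unit = f"{lid} (ALT)", f"alt-{unit}"
                lab_rows.append((pat_ids[p], date_str, name, f"{val:.4f}", unit))
            else:
                strings = _POS_STRINGS if lab_pos[e] else _NEG_STRINGS
                raw = strings[int(rng.integers(len(strings)))]
                lab_rows.append((pat_ids[p], date_str, lid, raw, ""))

    tables = EventTables(
        patients=pd.DataFrame(
            {
                "patient_id": pat_ids,
                "birth_date": [str(np.datetime64(int(bd), "D")) for bd in birth_days],
                "sex": sex,
            }
        ),
        encounters=pd.DataFrame(
            enc_rows, columns=["encounter_id", "patient_id", "date", "type", "status"]
        ),
        diagnoses=pd.DataFrame(
            dx_rows, columns=["encounter_id", "patient_id", "date", "icd10_code"]
        ),
        labs=pd.DataFrame(
            lab_rows, columns=["patient_id", "date", "lab_name", "raw_value", "unit"]
        ),
    )
    for df, col in ((tables.patients, "birth_date"), (tables.encounters, "date"),
                    (tables.diagnoses, "date"), (tables.labs, "date")):
        df[col] = pd.to_datetime(df[col])
    return tables, truth


def effective_weights(truth: GroundTruth) -> pd.DataFrame:
    """Ground-truth weights rescaled to comparable (per-standard-deviation)
    units: binary diagnosis/presence features unchanged, lab values
    multiplied by the lab's population standard deviation, age by the
    roughly 24-year spread of adult ages. Useful for ranking features or
    labels by how much signal they actually carry.
    """
    scaled = truth.weights.copy()
    for _, r in truth.lab_registry.iterrows():
        col = f"lab_value:{r['lab_id']}"
        if col in scaled.columns:
            scaled[col] = scaled[col] * r["sd"]
    if "demo:age" in scaled.columns:
        scaled["demo:age"] = scaled["demo:age"] * 24.0
    return scaled


def harmonization_tables(truth: GroundTruth) -> pd.DataFrame:
    """Unit/name conversion table matching the generator's emitted variants.

    Rows map (lab_name, unit) to (lab_id, kind, canonical_unit, factor);
    the factor converts an emitted value back to canonical units.
    """
    rows = []
    for _, r in truth.lab_registry.iterrows():
        if r["kind"] == "numeric":
            rows.append((r["lab_id"], r["canonical_unit"], r["lab_id"], "numeric",
                         r["canonical_unit"], 1.0))
            if r["confused"]:
                rows.append((f"{r['lab_id']} (ALT)", f"alt-{r['canonical_unit']}",
                             r["lab_id"], "numeric", r["canonical_unit"],
                             1.0 / r["confusion_factor"]))
        else:
            rows.append((r["lab_id"], "", r["lab_id"], "nonnumeric", "", 1.0))
    return pd.DataFrame(
        rows, columns=["lab_name", "unit", "lab_id", "kind", "canonical_unit", "factor"]
    )


def cci_table(truth: GroundTruth) -> pd.DataFrame:
    """Chronic-condition-indicator mapping for the synthetic alphabet.

    Mirrors the shape of the published chronic/acute indicator file:
    one row per code prefix with a chronic flag.
    """
    return pd.DataFrame(
        {
            "code": list(truth.chronic.index),
            "chronic_flag": ["chronic" if v else "acute" for v in truth.chronic],
        }
    )
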