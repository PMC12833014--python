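"""Synthetic spontaneous-report databases with known ground truth.

The generator emulates a FAERS-like reporting stream for a configurable
drug catalog: per-case demographics, multi-drug exposure reported under
brand or generic aliases, duplicate case versions, a mix of reporter
qualifications, adverse-event occurrence with injected drug-event relative
risks, and per-drug-category time-to-onset (latency) distributions.  Every
stochastic choice flows from one :class:`numpy.random.Generator` seeded
from the config, so output is bit-identical for identical seeds.

Model of event occurrence: a case exposed to an injected drug g develops
the target event with probability ``min(1, RR_g * background)``; with
several injected drugs on board the largest RR applies; unexposed cases use
the background rate alone.  Ground truth (exposures, events, the injected
signal set) is frozen *before* duplication and missingness are applied.

Latency is lognormal per drug category, parameterized by its target mean
in days and the log-scale standard deviation (default 1.0); only means are
pinned by the emulated study, the family and spread are generator choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .faers_io import apply_schema

__all__ = [
    "DrugSpec", "LatencySpec", "SynthConfig", "GroundTruth",
    "generate_reports", "default_config", "recovery_config",
    "drug_name_map", "drug_category_map", "write_ground_truth",
    "DEFAULT_EVENT_TERMS", "DEFAULT_LATENCY_MODEL",
]

DEFAULT_EVENT_TERMS = (
    "Vitreous floaters", "Vitreous opacities", "Myodesopsia", "Vitreous haze",
)

FILLER_PTS = ("Headache", "Nausea", "Fatigue", "Dizziness", "Rash",
              "Arthralgia", "Pyrexia", "Diarrhoea")

#: per-category lognormal latency means (days); antimicrobial shortest,
#: hormonal longest, ocular slower than the non-ocular average.
DEFAULT_LATENCY_MODEL = {
    "ocular": ("lognormal", 203.49, 1.0),
    "oncology": ("lognormal", 120.0, 1.0),
    "hormonal": ("lognormal", 409.16, 1.0),
    "antimicrobial": ("lognormal", 43.62, 1.0),
    "immunological": ("lognormal", 180.0, 1.0),
    "other": ("lognormal", 140.0, 1.0),
}

DEFAULT_REPORTER_MIX = {
    "MD": 0.52, "OT": 0.15, "HP": 0.12, "PH": 0.07, "CN": 0.10, "LW": 0.04,
}

DEFAULT_MISSINGNESS = {
    "age": 0.15, "wt": 0.25, "sex": 0.05, "event_dt": 0.10,
    "start_dt": 0.20, "route": 0.20, "occp_cod": 0.02,
}

COUNTRIES = ("US", "JP", "CA", "GB", "DE", "FR", "AU", "CN", "OTHER")
COUNTRY_P = (0.539, 0.090, 0.075, 0.056, 0.039, 0.027, 0.026, 0.013, 0.135)

OUTCOME_CODES = ("OT", "HO", "DS", "DE", "LT", "RI")
OUTCOME_P = (0.705, 0.177, 0.081, 0.018, 0.014, 0.005)

CATEGORY_ROUTES = {
    "ocular": ("Intraocular", "Ophthalmic"),
    "oncology": ("Oral", "Intravenous"),
    "hormonal": ("Intraocular", "Oral", "Intramuscular"),
    "antimicrobial": ("Oral", "Intravenous"),
    "immunological": ("Oral", "Subcutaneous"),
    "other": ("Oral", "Nasal", "Intramuscular"),
}

CATEGORY_INDICATIONS = {
    "ocular": "Neovascular age-related macular degeneration",
    "oncology": "Non-small cell lung cancer",
    "hormonal": "Macular oedema",
    "antimicrobial": "Infection",
    "immunological": "Multiple sclerosis",
    "other": "Erectile dysfunction",
}


@dataclass(frozen=True)
class DrugSpec:
    """One catalog entry: generic name, brand aliases, category, exposure."""

    generic: str
    brands: tuple[str, ...]
    category: str
    exposure_p: float


@dataclass(frozen=True)
class LatencySpec:
    """Lognormal latency: target arithmetic mean (days) and log-scale sd."""

    mean_days: float
    log_sd: float = 1.0

    @property
    def mu(self) -> float:
        """Location parameter giving the target arithmetic mean."""
        return float(np.log(self.mean_days) - 0.5 * self.log_sd**2)


@dataclass
class SynthConfig:
    n_cases: int
    drug_catalog: list[DrugSpec]
    event_terms: tuple[str, ...] = DEFAULT_EVENT_TERMS
    background_p: float = 0.003
    injected_rr: dict[str, float] = field(default_factory=dict)
    duplicate_rate: float = 0.10
    reporter_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_REPORTER_MIX))
    latency_model: dict[str, LatencySpec] = field(default_factory=dict)
    missingness: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    seed: int = 0

    def __post_init__(self):
        if not self.latency_model:
            self.latency_model = {k: LatencySpec(v[1], v[2])
                                  for k, v in DEFAULT_LATENCY_MODEL.items()}
        self.validate()

    def validate(self):
        if self.n_cases <= 0:
            raise ConfigurationError("n_cases must be positive")
        if not self.drug_catalog:
            raise ConfigurationError("drug catalog is empty")
        if not self.event_terms:
            raise ConfigurationError("event_terms is empty")
        if not 0.0 <= self.background_p <= 1.0:
            raise ConfigurationError("background_p must lie in [0, 1]")
        if not 0.0 <= self.duplicate_rate < 1.0:
            raise ConfigurationError("duplicate_rate must lie in [0, 1)")
        generics = {d.generic for d in self.drug_catalog}
        for d in self.drug_catalog:
            if not 0.0 <= d.exposure_p <= 1.0:
                raise ConfigurationError(
                    f"exposure probability of {d.generic!r} outside [0, 1]")
            if d.category not in self.latency_model:
                raise ConfigurationError(
                    f"no latency model for category {d.category!r}")
        for g, rr in self.injected_rr.items():
            if g not in generics:
                raise ConfigurationError(f"injected drug {g!r} not in catalog")
            if rr < 0:
                raise ConfigurationError(f"relative risk of {g!r} is negative")
        for f_, p in self.missingness.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"missingness for {f_!r} outside [0, 1]")
        total = sum(self.reporter_mix.values())
        if not self.reporter_mix or total <= 0:
            raise ConfigurationError("reporter_mix must have positive mass")


@dataclass
class GroundTruth:
    """Pre-duplication, pre-missingness truth for one generated database."""

    signals: frozenset[str]          # injected drugs with RR > 1
    exposure: pd.DataFrame           # bool, index caseid, one column per generic
    event: pd.Series                 # bool, index caseid
    config: SynthConfig


def _yyyymmdd(days: np.ndarray) -> np.ndarray:
    """Convert datetime64[D] array to yyyymmdd integers."""
    di = pd.DatetimeIndex(days)
    return (di.year * 10000 + di.month * 100 + di.day).to_numpy()


def generate_reports(config: SynthConfig):
    """Generate the six report tables and the ground truth.

    Returns ``(tables, truth)`` where ``tables`` maps table name to
    DataFrame in the :mod:`pvsignal.faers_io` schemas.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    caseid = np.arange(10_000_001, 10_000_001 + n, dtype=np.int64)

    # --- exposure and event truth -------------------------------------
    expo = {d.generic: rng.random(n) < d.exposure_p for d in config.drug_catalog}
    eff = np.full(n, -np.inf)
    any_inj = np.zeros(n, dtype=bool)
    for g, rr in config.injected_rr.items():
        m = expo[g]
        eff[m] = np.maximum(eff[m], rr)
        any_inj |= m
    eff = np.where(any_inj, eff, 1.0)
    p_event = np.clip(config.background_p * eff, 0.0, 1.0)
    event = rng.random(n) < p_event

    truth = GroundTruth(
        signals=frozenset(g for g, rr in config.injected_rr.items() if rr > 1),
        exposure=pd.DataFrame(expo, index=pd.Index(caseid, name="caseid")),
        event=pd.Series(event, index=pd.Index(caseid, name="caseid"), name="event"),
        config=config,
    )

    # --- demographics --------------------------------------------------
    age = np.clip(rng.normal(62.05, 17.58, n), 1, 100).round(0)
    wt = np.clip(rng.normal(75.21, 20.94, n), 30, 200).round(2)
    sex = rng.choice(np.array(["F", "M"]), n, p=[0.6188, 0.3812])
    country = rng.choice(np.array(COUNTRIES), n, p=COUNTRY_P)
    mix_keys = np.array(list(config.reporter_mix))
    mix_p = np.array(list(config.reporter_mix.values()), dtype=float)
    occp = rng.choice(mix_keys, n, p=mix_p / mix_p.sum())
    event_day = (np.datetime64("2004-01-01")
                 + rng.integers(0, 7670, n).astype("timedelta64[D]"))
    outc = rng.choice(np.array(OUTCOME_CODES), n, p=OUTCOME_P)

    # --- drug / therapy / indication rows ------------------------------
    drug_parts, ther_parts, indi_parts = [], [], []
    for seq, d in enumerate(config.drug_catalog, start=1):
        idx = np.nonzero(expo[d.generic])[0]
        k = idx.size
        if k == 0:
            continue
        aliases = np.array([d.generic, *d.brands])
        names = aliases[rng.integers(0, aliases.size, k)]
        names = np.where(rng.random(k) < 0.5, np.char.upper(names.astype(str)),
                         names.astype(str))
        routes = np.array(CATEGORY_ROUTES[d.category])
        route = routes[rng.integers(0, routes.size, k)]
        spec = config.latency_model[d.category]
        is_ev = event[idx]
        dur = np.empty(k)
        lat = rng.lognormal(spec.mu, spec.log_sd, k)
        dur[is_ev] = np.maximum(1.0, np.round(lat[is_ev]))
        dur[~is_ev] = np.maximum(1.0, np.round(rng.exponential(180.0, (~is_ev).sum())))
        start = event_day[idx] - dur.astype("timedelta64[D]")
        drug_parts.append(pd.DataFrame({
            "caseid": caseid[idx], "drug_seq": seq, "drugname": names,
            "route": route}))
        ther_parts.append(pd.DataFrame({
            "caseid": caseid[idx], "dsg_drug_seq": seq,
            "start_dt": _yyyymmdd(start)}))
        indi_parts.append(pd.DataFrame({
            "caseid": caseid[idx], "indi_drug_seq": seq,
            "indi_pt": CATEGORY_INDICATIONS[d.category]}))
    drug = (pd.concat(drug_parts, ignore_index=True) if drug_parts
            else pd.DataFrame(columns=["caseid", "drug_seq", "drugname", "route"]))
    ther = (pd.concat(ther_parts, ignore_index=True) if ther_parts
            else pd.DataFrame(columns=["caseid", "dsg_drug_seq", "start_dt"]))
    indi = (pd.concat(indi_parts, ignore_index=True) if indi_parts
            else pd.DataFrame(columns=["caseid", "indi_drug_seq", "indi_pt"]))

    # --- reactions ------------------------------------------------------
    terms = np.array(config.event_terms)
    ev_idx = np.nonzero(event)[0]
    reac_parts = [pd.DataFrame({
        "caseid": caseid[ev_idx],
        "pt": terms[rng.integers(0, terms.size, ev_idx.size)]})]
    n_fill = rng.integers(1, 3, n)
    fill_case = np.repeat(caseid, n_fill)
    fillers = np.array(FILLER_PTS)
    reac_parts.append(pd.DataFrame({
        "caseid": fill_case,
        "pt": fillers[rng.integers(0, fillers.size, fill_case.size)]}))
    reac = pd.concat(reac_parts, ignore_index=True)
    reac = reac.sort_values("caseid", kind="stable", ignore_index=True)

    # --- missingness (truth already frozen) -----------------------------
    miss = dict(config.missingness)
    age = np.where(rng.random(n) < miss.get("age", 0), np.nan, age)
    wt = np.where(rng.random(n) < miss.get("wt", 0), np.nan, wt)
    sex = np.where(rng.random(n) < miss.get("sex", 0), None, sex)
    occp = np.where(rng.random(n) < miss.get("occp_cod", 0), None, occp)
    event_dt = _yyyymmdd(event_day).astype(object)
    event_dt[rng.random(n) < miss.get("event_dt", 0)] = None
    route_col = drug["route"].to_numpy(dtype=object)
    route_col[rng.random(len(drug)) < miss.get("route", 0)] = None
    drug["route"] = route_col
    start_col = ther["start_dt"].to_numpy(dtype=object)
    start_col[rng.random(len(ther)) < miss.get("start_dt", 0)] = None
    ther["start_dt"] = start_col

    demo = pd.DataFrame({
        "caseid": caseid, "caseversion": 1, "event_dt": event_dt,
        "age": age, "sex": sex, "wt": wt, "reporter_country": country,
        "occp_cod": occp,
    })
    outc_df = pd.DataFrame({"caseid": caseid, "outc_cod": outc})

    # --- duplicate case versions ---------------------------------------
    n_dup = int(round(n * config.duplicate_rate))
    tables = {"demo": demo, "drug": drug, "reac": reac, "ther": ther,
              "indi": indi, "outc": outc_df}
    if n_dup > 0:
        dup_pos = rng.choice(n, size=n_dup, replace=False)
        dup_ids = caseid[dup_pos]
        dup_demo = demo.iloc[dup_pos].copy()
        dup_demo["caseversion"] = 2
        perturb = rng.random(n_dup) < 0.5
        dup_demo.loc[perturb, "wt"] = (
            dup_demo.loc[perturb, "wt"] + rng.normal(0, 1.0, int(perturb.sum()))
        ).round(2)
        tables["demo"] = pd.concat([demo, dup_demo], ignore_index=True)
        dup_set = set(dup_ids.tolist())
        for name in ("drug", "reac", "ther", "indi", "outc"):
            df = tables[name]
            part = df[df["caseid"].isin(dup_set)].copy()
            part["_version"] = 2
            df = df.copy()
            df["_version"] = 1
            tables[name] = pd.concat([df, part], ignore_index=True)
    else:
        for name in ("drug", "reac", "ther", "indi", "outc"):
            tables[name] = tables[name].assign(_version=1)
        tables["demo"] = demo

    # primaryid encodes (caseid, version), as in real quarter files
    demo_t = tables["demo"]
    demo_t.insert(0, "primaryid", demo_t["caseid"] * 10 + demo_t["caseversion"])
    for name in ("drug", "reac", "ther", "indi", "outc"):
        df = tables[name]
        version = df.pop("_version") if "_version" in df else 1
        df.insert(0, "primaryid", df["caseid"] * 10 + version)
        tables[name] = apply_schema(df, name)
    tables["demo"] = apply_schema(demo_t, "demo")
    return tables, truth


# --------------------------------------------------------------------------
# ready-made configurations


def _default_catalog() -> list[DrugSpec]:
    mk = DrugSpec
    return [
        mk("ranibizumab", ("Lucentis",), "ocular", 0.020),
        mk("brolucizumab", ("Beovu",), "ocular", 0.004),
        mk("aflibercept", ("Eylea",), "ocular", 0.020),
        mk("faricimab", ("Vabysmo",), "ocular", 0.005),
        mk("latanoprost", ("Xalatan",), "ocular", 0.010),
        mk("bevacizumab", ("Avastin",), "oncology", 0.015),
        mk("crizotinib", ("Xalkori",), "oncology", 0.006),
        mk("dexamethasone", ("Ozurdex", "Decadron"), "hormonal", 0.010),
        mk("triamcinolone", ("Kenalog",), "hormonal", 0.008),
        mk("finasteride", ("Propecia", "Proscar"), "hormonal", 0.010),
        mk("ciprofloxacin", ("Cipro",), "antimicrobial", 0.030),
        mk("voriconazole", ("Vfend",), "antimicrobial", 0.008),
        mk("terbinafine", ("Lamisil",), "antimicrobial", 0.010),
        mk("fingolimod", ("Gilenya",), "immunological", 0.008),
        mk("cyclosporine", ("Neoral", "Sandimmune"), "immunological", 0.010),
        mk("oxymetazoline", ("Afrin",), "other", 0.005),
        mk("sildenafil", ("Viagra",), "other", 0.015),
        mk("botulinum toxin type a", ("Botox",), "other", 0.010),
    ]


DEFAULT_INJECTED_RR = {
    "ranibizumab": 20.0, "brolucizumab": 50.0, "dexamethasone": 20.0,
    "triamcinolone": 10.0, "crizotinib": 12.0, "ciprofloxacin": 8.0,
    "voriconazole": 6.0, "fingolimod": 8.0, "oxymetazoline": 15.0,
}


def default_config(n_cases: int = 60_000, seed: int = 0,
                   injected_rr: dict[str, float] | None = None) -> SynthConfig:
    """Study-profile configuration: a small named catalog spanning the six
    drug categories, with injected signals in each category."""
    return SynthConfig(
        n_cases=n_cases,
        drug_catalog=_default_catalog(),
        injected_rr=DEFAULT_INJECTED_RR if injected_rr is None else injected_rr,
        seed=seed,
    )


def recovery_config(n_cases: int = 100_000, n_drugs: int = 50,
                    signal_positions: tuple[int, ...] = (5, 25, 45),
                    rr: float = 20.0, seed: int = 0) -> SynthConfig:
    """Anonymous-catalog configuration for signal-recovery experiments.

    ``n_drugs`` drugs with exposure probabilities spread linearly over
    [0.004, 0.030] and categories cycling through the six labels; drugs at
    ``signal_positions`` get relative risk ``rr`` (pass ``rr=1`` or empty
    positions for an all-null database).
    """
    cats = list(DEFAULT_LATENCY_MODEL)
    catalog = [
        DrugSpec(f"drug{i:02d}", (f"BRAND{i:02d}",), cats[i % len(cats)],
                 0.004 + 0.026 * i / max(n_drugs - 1, 1))
        for i in range(n_drugs)
    ]
    injected = {catalog[i].generic: rr for i in signal_positions if rr != 1.0}
    return SynthConfig(n_cases=n_cases, drug_catalog=catalog,
                       injected_rr=injected, seed=seed)


def config_from_dict(d: dict) -> SynthConfig:
    """Build a :class:`SynthConfig` from a plain (JSON-style) dict.

    Schema: ``n_cases`` (int, required); ``drug_catalog`` (required) is a
    list of ``{generic, brands, category, exposure_p}``; ``latency_model``
    maps category to ``{mean_days, log_sd}``; the remaining keys mirror the
    dataclass fields and fall back to their defaults.
    """
    if "n_cases" not in d or "drug_catalog" not in d:
        raise ConfigurationError("config needs 'n_cases' and 'drug_catalog'")
    catalog = [DrugSpec(c["generic"], tuple(c.get("brands", ())),
                        c["category"], float(c["exposure_p"]))
               for c in d["drug_catalog"]]
    kwargs = {}
    for key in ("event_terms", "background_p", "injected_rr",
                "duplicate_rate", "reporter_mix", "missingness", "seed"):
        if key in d:
            kwargs[key] = tuple(d[key]) if key == "event_terms" else d[key]
    if "latency_model" in d:
        kwargs["latency_model"] = {
            cat: LatencySpec(float(v["mean_days"]), float(v.get("log_sd", 1.0)))
            for cat, v in d["latency_model"].items()}
    return SynthConfig(n_cases=int(d["n_cases"]), drug_catalog=catalog, **kwargs)


def drug_name_map(catalog: list[DrugSpec]) -> pd.DataFrame:
    """Brand/generic -> generic normalization map for a catalog."""
    rows = []
    for d in catalog:
        rows.append({"name": d.generic, "generic": d.generic})
        for b in d.brands:
            rows.append({"name": b, "generic": d.generic})
    return pd.DataFrame(rows)


def drug_category_map(catalog: list[DrugSpec]) -> pd.DataFrame:
    """Generic -> category map for a catalog."""
    return pd.DataFrame([{"generic": d.generic, "category": d.category}
                         for d in catalog])


def write_ground_truth(truth: GroundTruth, directory) -> None:
    """Write the truth sidecars: per-case exposures/events and signal list."""
    import os

    os.makedirs(directory, exist_ok=True)
    cases = truth.exposure.copy()
    cases.insert(0, "event", truth.event)
    cases.to_csv(os.path.join(directory, "ground_truth_cases.csv"))
    pd.DataFrame({
        "drug": sorted(truth.config.injected_rr),
        "rr": [truth.config.injected_rr[g] for g in sorted(truth.config.injected_rr)],
    }).to_csv(os.path.join(directory, "ground_truth_signals.csv"), index=False)
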