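"""Data cleaning for spontaneous-report tables, with attrition accounting.

The cleaning flow mirrors standard pharmacovigilance practice on FAERS-like
extracts: (1) drop records without a case identifier, (2) deduplicate to
one record per case keeping the greatest version stamp, (3) keep reports
from healthcare professionals only (MD/PH/OT/HP), (4) identify event cases
by a narrow preferred-term list, (5) merge brand and generic drug names via
a user-supplied map, and (6) exclude drugs with fewer than three event
cases from signal analysis.  Every removed record is attributed to exactly
one step in an :class:`AttritionLog`.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MapFormatError

__all__ = [
    "DEFAULT_PT_TERMS", "DEFAULT_REPORTERS", "AttritionLog", "CleanDatabase",
    "deduplicate", "filter_reporters", "select_event_cases", "load_drug_map",
    "normalize_drugs", "min_count_filter", "clean_pipeline",
    "load_category_map", "parse_yyyymmdd",
]

#: narrow preferred-term scope for the vitreous-opacity event of interest
DEFAULT_PT_TERMS = ("vitreous floaters", "vitreous opacities",
                    "myodesopsia", "vitreous haze")

#: healthcare-professional reporter qualification codes
DEFAULT_REPORTERS = frozenset({"MD", "PH", "OT", "HP"})


@dataclass
class AttritionStep:
    step: str
    n_in: int
    n_out: int
    reason: str


@dataclass
class AttritionLog:
    steps: list[AttritionStep] = field(default_factory=list)

    def add(self, step: str, n_in: int, n_out: int, reason: str):
        self.steps.append(AttritionStep(step, int(n_in), int(n_out), reason))

    def validate(self):
        """Check conservation: each step starts where the previous ended."""
        for prev, cur in zip(self.steps, self.steps[1:]):
            if prev.n_out != cur.n_in:
                raise ValueError(
                    f"attrition chain broken between {prev.step!r} "
                    f"({prev.n_out} out) and {cur.step!r} ({cur.n_in} in)")

    @property
    def total_removed(self) -> int:
        return sum(s.n_in - s.n_out for s in self.steps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.steps])

    def __str__(self) -> str:
        lines = [f"{s.step}: {s.n_in} -> {s.n_out} ({s.reason})"
                 for s in self.steps]
        return "\n".join(lines)


def parse_yyyymmdd(series: pd.Series) -> pd.Series:
    """Parse 8-digit integer dates to datetimes (NaT on missing/invalid)."""
    s = series.astype("Int64").astype("string")
    return pd.to_datetime(s, format="%Y%m%d", errors="coerce")


def deduplicate(demo: pd.DataFrame, key: str = "caseid",
                version_col: str = "caseversion",
                log: AttritionLog | None = None) -> pd.DataFrame:
    """Keep one record per ``key``: the greatest version stamp wins.

    Ties (and missing versions, sorted lowest) are broken by last occurrence
    in file order — a stable sort on the version column preserves file order
    within equal stamps.  Records with a missing ``key`` are dropped first,
    with their own attrition entry.
    """
    log = log if log is not None else AttritionLog()
    n0 = len(demo)
    demo1 = demo[demo[key].notna()]
    log.add("drop_missing_id", n0, len(demo1), "missing case identifier")
    s = demo1.sort_values(version_col, kind="stable", na_position="first")
    out = s.drop_duplicates(subset=key, keep="last").sort_index()
    log.add("deduplicate", len(demo1), len(out),
            f"kept greatest {version_col} per {key}")
    return out


def filter_reporters(demo: pd.DataFrame,
                     allowed: frozenset[str] = DEFAULT_REPORTERS,
                     log: AttritionLog | None = None) -> pd.DataFrame:
    """Keep reports whose qualification code is in ``allowed``.

    Missing qualification is excluded (non-professional by default).
    """
    if not allowed:
        raise ValueError("allowed reporter codes must be nonempty")
    log = log if log is not None else AttritionLog()
    out = demo[demo["occp_cod"].isin(allowed)]
    log.add("filter_reporters", len(demo), len(out),
            f"reporter qualification not in {{{', '.join(sorted(allowed))}}}")
    return out


def _norm_text(s: pd.Series) -> pd.Series:
    return s.astype("string").str.strip().str.casefold()


def select_event_cases(reac: pd.DataFrame,
                       pt_list=DEFAULT_PT_TERMS) -> tuple[frozenset, frozenset]:
    """Partition case ids into (event cases, non-cases) by narrow PT scope.

    A case is an event case iff any of its PTs equals a listed term after
    trimming and case-folding (exact string match, no fuzzy matching).
    """
    if not pt_list:
        raise ValueError("pt_list must be nonempty")
    targets = {t.strip().casefold() for t in pt_list}
    hit = _norm_text(reac["pt"]).isin(targets)
    event = frozenset(reac.loc[hit, "caseid"].tolist())
    all_ids = frozenset(reac["caseid"].tolist())
    return event, all_ids - event


def load_drug_map(source) -> dict[str, str]:
    """Load a brand/generic -> generic map from CSV path or DataFrame.

    Expected columns ``name, generic``; matching is on trimmed, case-folded
    names.  A row with a missing field raises :class:`MapFormatError`
    naming the row.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    if not {"name", "generic"} <= set(df.columns):
        raise MapFormatError("drug map needs columns 'name' and 'generic'")
    mapping = {}
    for i, row in enumerate(df.itertuples(index=False)):
        name, generic = row.name, row.generic
        if pd.isna(name) or pd.isna(generic) or not str(name).strip() \
                or not str(generic).strip():
            raise MapFormatError(f"malformed drug-map row {i}: {row}", row=i)
        mapping[str(name).strip().casefold()] = str(generic).strip().casefold()
    return mapping


def load_category_map(source=None) -> dict[str, str]:
    """Generic -> category map; defaults to the packaged pre-classified list."""
    if source is None:
        ref = importlib.resources.files("pvsignal") / "data/drug_categories.csv"
        with importlib.resources.as_file(ref) as path:
            df = pd.read_csv(path)
    elif isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source)
    return {str(g).strip().casefold(): str(c).strip()
            for g, c in zip(df["generic"], df["category"])}


def normalize_drugs(drug: pd.DataFrame,
                    name_map: dict[str, str] | None) -> pd.DataFrame:
    """Add a ``generic`` column from the verbatim ``drugname``.

    Unmapped names pass through verbatim (case-folded) with a single
    summary warning listing them.
    """
    key = _norm_text(drug["drugname"])
    if name_map:
        mapped = key.map(name_map)
        unmapped = sorted(key[mapped.isna() & key.notna()].unique())
        if unmapped:
            warnings.warn(
                f"{len(unmapped)} verbatim drug name(s) not in map, kept "
                f"as-is: {', '.join(unmapped[:10])}"
                + ("..." if len(unmapped) > 10 else ""))
        generic = mapped.fillna(key)
    else:
        generic = key
    out = drug.copy()
    out["generic"] = generic
    return out


def min_count_filter(counts, threshold: int = 3) -> list[str]:
    """Drugs retained for signal analysis: event-case count >= threshold.

    'Fewer than *threshold*' are excluded, so the boundary count is kept.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    items = counts.items() if hasattr(counts, "items") else counts
    return sorted(g for g, c in items if c >= threshold)


@dataclass
class CleanDatabase:
    """Deduplicated, reporter-filtered database ready for signal analysis."""

    cases: pd.DataFrame            # index caseid: demographics + event_dt
    exposures: pd.DataFrame        # caseid, generic, category, route, start_dt, indication
    event_case_ids: frozenset
    pt_list: tuple[str, ...]
    attrition: AttritionLog
    drug_event_counts: pd.Series   # event-case count per generic (all drugs)
    retained_drugs: tuple[str, ...]
    category_map: dict[str, str] = field(default_factory=dict)

    @property
    def case_ids(self) -> np.ndarray:
        return self.cases.index.to_numpy()

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    @property
    def drugs(self) -> tuple[str, ...]:
        return self.retained_drugs

    def exposed_case_ids(self, drug: str) -> frozenset:
        sel = self.exposures.loc[self.exposures["generic"] == drug, "caseid"]
        return frozenset(sel.tolist())

    def drug_category(self, drug: str) -> str:
        return self.category_map.get(drug, "other")

    def case_covariates(self, drugs=None) -> pd.DataFrame:
        """Per-case covariate table for case/non-case regression.

        Route and indication are taken from the case's first drug row;
        ``time_days`` is days from the earliest therapy start to the event
        date; one 0/1 indicator column per requested drug (defaults to the
        retained drugs); ``event`` is the response.
        """
        drugs = list(drugs) if drugs is not None else list(self.retained_drugs)
        df = self.cases.copy()
        first = (self.exposures.groupby("caseid")[["route", "indication"]]
                 .first())
        df = df.join(first)
        starts = self.exposures.assign(
            start=parse_yyyymmdd(self.exposures["start_dt"])
        ).groupby("caseid")["start"].min()
        event_date = parse_yyyymmdd(df["event_dt"])
        df["time_days"] = (event_date - df.index.map(starts)).dt.days.astype("float")
        for g in drugs:
            ids = self.exposed_case_ids(g)
            df[f"drug:{g}"] = df.index.isin(ids).astype(int)
        df["event"] = df.index.isin(self.event_case_ids).astype(int)
        return df


_CASES_SCHEMA = {"caseversion": "int64", "event_dt": "Int64",
                 "age": "float64", "sex": "string", "wt": "float64",
                 "reporter_country": "string", "occp_cod": "string"}
_EXPO_SCHEMA = {"caseid": "int64", "generic": "string", "route": "string",
                "start_dt": "Int64", "indication": "string",
                "category": "string"}


def save_clean_database(db: CleanDatabase, directory) -> None:
    """Persist a cleaned database as CSV + JSON sidecars."""
    import json
    import os

    os.makedirs(directory, exist_ok=True)
    db.cases.to_csv(os.path.join(directory, "cases.csv"))
    db.exposures.to_csv(os.path.join(directory, "exposures.csv"), index=False)
    db.attrition.to_frame().to_csv(os.path.join(directory, "attrition.csv"),
                                   index=False)
    with open(os.path.join(directory, "attrition.txt"), "w") as fh:
        fh.write(str(db.attrition) + "\n")
    meta = {
        "pt_list": list(db.pt_list),
        "retained_drugs": list(db.retained_drugs),
        "event_case_ids": sorted(int(i) for i in db.event_case_ids),
        "drug_event_counts": {str(k): int(v)
                              for k, v in db.drug_event_counts.items()},
        "category_map": db.category_map,
    }
    with open(os.path.join(directory, "meta.json"), "w") as fh:
        json.dump(meta, fh)


def load_clean_database(directory) -> CleanDatabase:
    """Load a database written by :func:`save_clean_database`."""
    import json
    import os

    cases = pd.read_csv(os.path.join(directory, "cases.csv"),
                        index_col="caseid")
    for col, dt in _CASES_SCHEMA.items():
        cases[col] = cases[col].astype(dt)
    exposures = pd.read_csv(os.path.join(directory, "exposures.csv"))
    for col, dt in _EXPO_SCHEMA.items():
        exposures[col] = exposures[col].astype(dt)
    att = pd.read_csv(os.path.join(directory, "attrition.csv"))
    log = AttritionLog([AttritionStep(**row) for row in
                        att.to_dict(orient="records")])
    with open(os.path.join(directory, "meta.json")) as fh:
        meta = json.load(fh)
    counts = pd.Series(meta["drug_event_counts"], dtype=int)
    counts.index.name = "generic"
    return CleanDatabase(
        cases=cases, exposures=exposures,
        event_case_ids=frozenset(meta["event_case_ids"]),
        pt_list=tuple(meta["pt_list"]), attrition=log,
        drug_event_counts=counts,
        retained_drugs=tuple(meta["retained_drugs"]),
        category_map=meta["category_map"],
    )


def clean_pipeline(tables: dict[str, pd.DataFrame],
                   drug_map=None,
                   category_map=None,
                   pt_list=DEFAULT_PT_TERMS,
                   reporters: frozenset[str] = DEFAULT_REPORTERS,
                   min_count: int = 3,
                   dedup_key: str = "caseid") -> CleanDatabase:
    """Run the full cleaning flow and assemble a :class:`CleanDatabase`.

    ``dedup_key="caseid"`` gives unique-subject granularity (default);
    ``"primaryid"`` keeps every report version (per-report granularity).
    ``drug_map`` / ``category_map`` accept a path, DataFrame, preloaded
    dict, or None (identity normalization / packaged categories).
    """
    log = AttritionLog()
    demo = tables["demo"]
    log.add("load", len(demo), len(demo), "raw demographic records")
    demo = deduplicate(demo, key=dedup_key, log=log)
    demo = filter_reporters(demo, frozenset(reporters), log=log)
    log.validate()
    kept = set(demo["primaryid"].tolist())

    def child(name):
        df = tables[name]
        return df[df["primaryid"].isin(kept)]

    reac = child("reac")
    event_ids, _ = select_event_cases(reac, pt_list)

    if drug_map is not None and not isinstance(drug_map, dict):
        drug_map = load_drug_map(drug_map)
    if category_map is None or not isinstance(category_map, dict):
        category_map = load_category_map(category_map)

    drug = child("drug")
    ther = child("ther").rename(columns={"dsg_drug_seq": "drug_seq"})
    indi = child("indi").rename(columns={"indi_drug_seq": "drug_seq"})
    drug = drug.merge(ther[["primaryid", "drug_seq", "start_dt"]],
                      on=["primaryid", "drug_seq"], how="left")
    drug = drug.merge(indi[["primaryid", "drug_seq", "indi_pt"]],
                      on=["primaryid", "drug_seq"], how="left")
    drug = normalize_drugs(drug, drug_map)
    # one exposure per (case, generic): earliest therapy start, first
    # non-missing route/indication
    exposures = (drug.sort_values(["caseid", "generic"], kind="stable")
                 .groupby(["caseid", "generic"], as_index=False)
                 .agg(route=("route", "first"),
                      start_dt=("start_dt", "min"),
                      indication=("indi_pt", "first")))
    exposures["category"] = (exposures["generic"].map(category_map)
                             .fillna("other"))

    case_ids = set(demo["caseid"].tolist())
    event_ids = frozenset(e for e in event_ids if e in case_ids)
    ev_expo = exposures[exposures["caseid"].isin(event_ids)]
    counts = ev_expo.groupby("generic")["caseid"].nunique()
    retained = min_count_filter(counts, min_count)

    cases = demo.set_index("caseid")[
        ["caseversion", "event_dt", "age", "sex", "wt",
         "reporter_country", "occp_cod"]]
    return CleanDatabase(
        cases=cases,
        exposures=exposures,
        event_case_ids=event_ids,
        pt_list=tuple(pt_list),
        attrition=log,
        drug_event_counts=counts,
        retained_drugs=tuple(retained),
        category_map=category_map,
    )
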