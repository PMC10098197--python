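"""Summary surfaces: frequency, herd usage, metric shares, WHO-CIA, rates.

All percentages are rounded half-up to two decimals at this layer only;
the metric layer carries full precision. A "product administered" is one
treatment event's product, so frequency totals equal the number of events.

Every table can be built either from validated events plus a catalogue or
directly from an event-level metrics frame (which already carries the
substance, class, WHO category, indication and herd of each event); the
two routes produce identical tables, which is what lets reports be
regenerated from ``metrics.csv`` without recomputation.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .catalogue import Catalogue, WhoCategory
from .errors import AmuError, ValidationError
from .records import Herd, HerdType, Indication, TreatmentEvent

__all__ = [
    "round_half_up",
    "events_frame",
    "product_frequency_table",
    "frequency_from_metrics",
    "herd_usage_table",
    "herd_usage_from_metrics",
    "share_of_total",
    "cia_summary",
    "cia_from_metrics",
    "condition_case_summary",
    "herd_type_comparison",
    "adur_table",
    "HerdTypeComparison",
    "write_reports",
]

INDICATIONS = [i.value for i in Indication]

_GROUP_COLUMNS = {
    "substance": "substance",
    "class": "am_class",
    "amClass": "am_class",
    "whoCategory": "who_category",
    "who_category": "who_category",
}
_METRIC_COLUMNS = {"nADD": "n_add", "nUADD": "n_uadd", "n_add": "n_add",
                   "n_uadd": "n_uadd"}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (2 dp by default), matching printed tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _pct(n: float, total: float) -> float:
    return round_half_up(100.0 * n / total) if total else 0.0


def events_frame(
    events: list[TreatmentEvent], catalogue: Catalogue
) -> pd.DataFrame:
    """Long-form frame of events annotated with substance/class/category."""
    rows = []
    for e in events:
        sub = catalogue.dose_determining(e.product_id).substance
        rows.append(
            {
                "event_id": e.event_id,
                "herd_id": e.herd_id,
                "indication": e.indication.value,
                "substance": sub,
                "am_class": catalogue.substance(sub).am_class,
                "who_category": catalogue.who_category(sub).value,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["event_id", "herd_id", "indication", "substance", "am_class",
                 "who_category"],
    )


# -- frequency -------------------------------------------------------------

def _frequency(frame: pd.DataFrame) -> pd.DataFrame:
    cols = ["substance", "am_class", "n_products", "pct_products"] + [
        f"{p}_{i.lower()}" for i in INDICATIONS for p in ("n", "pct")
    ]
    if frame.empty:
        return pd.DataFrame(columns=cols)
    grp = frame.groupby(["substance", "am_class"], sort=False)
    df = grp.size().rename("n_products").reset_index()
    for ind in INDICATIONS:
        sub = frame[frame["indication"] == ind]
        counts = sub.groupby("substance").size()
        df[f"n_{ind.lower()}"] = [
            int(counts.get(s, 0)) for s in df["substance"]
        ]
    total = int(df["n_products"].sum())
    df["pct_products"] = [_pct(n, total) for n in df["n_products"]]
    for ind in INDICATIONS:
        col_total = int(df[f"n_{ind.lower()}"].sum())
        df[f"pct_{ind.lower()}"] = [
            _pct(n, col_total) for n in df[f"n_{ind.lower()}"]
        ]
    return (
        df[cols]
        .sort_values(["n_products", "substance"], ascending=[False, True],
                     kind="stable")
        .reset_index(drop=True)
    )


def product_frequency_table(
    events: list[TreatmentEvent], catalogue: Catalogue
) -> pd.DataFrame:
    """Product administrations per substance, overall and by indication."""
    return _frequency(events_frame(events, catalogue))


def frequency_from_metrics(metrics: pd.DataFrame) -> pd.DataFrame:
    """Same table rebuilt from an event-level metrics frame."""
    return _frequency(metrics)


# -- herd usage ------------------------------------------------------------

def _herd_usage(frame: pd.DataFrame, herds: list[Herd]) -> pd.DataFrame:
    herd_ids = {h.herd_id for h in herds}
    unknown = set(frame["herd_id"]) - herd_ids
    if unknown:
        raise ValidationError(
            f"events reference unknown herd(s): {sorted(unknown)}"
        )
    n_herds = len(herd_ids)
    rows = []
    for (sub, am_class), grp in frame.groupby(
        ["substance", "am_class"], sort=False
    ):
        row = {
            "substance": sub,
            "am_class": am_class,
            "n_herds": grp["herd_id"].nunique(),
            "pct_herds": _pct(grp["herd_id"].nunique(), n_herds),
        }
        for ind in INDICATIONS:
            k = grp.loc[grp["indication"] == ind, "herd_id"].nunique()
            row[f"n_herds_{ind.lower()}"] = int(k)
            row[f"pct_herds_{ind.lower()}"] = _pct(k, n_herds)
        rows.append(row)
    cols = ["substance", "am_class", "n_herds", "pct_herds"] + [
        f"{p}_{i.lower()}" for i in INDICATIONS
        for p in ("n_herds", "pct_herds")
    ]
    if not rows:
        return pd.DataFrame(columns=cols)
    return (
        pd.DataFrame(rows)[cols]
        .sort_values(["n_herds", "substance"], ascending=[False, True],
                     kind="stable")
        .reset_index(drop=True)
    )


def herd_usage_table(
    events: list[TreatmentEvent],
    herds: list[Herd],
    catalogue: Catalogue,
) -> pd.DataFrame:
    """Herds using each substance (a herd counts once per substance)."""
    return _herd_usage(events_frame(events, catalogue), herds)


def herd_usage_from_metrics(
    metrics: pd.DataFrame, herds: list[Herd]
) -> pd.DataFrame:
    return _herd_usage(metrics, herds)


# -- shares ----------------------------------------------------------------

def share_of_total(
    metrics: pd.DataFrame,
    group_by: str = "substance",
    metric: str = "nADD",
) -> pd.DataFrame:
    """Percentage share of a summed metric per substance/class/WHO category.

    Invariant under uniform rescaling of the metric; shares are half-up
    rounded to 2 dp and sum to 100 up to rounding slack.
    """
    try:
        group_col = _GROUP_COLUMNS[group_by]
        metric_col = _METRIC_COLUMNS[metric]
    except KeyError:
        raise AmuError(
            f"unknown grouping {group_by!r} or metric {metric!r}"
        ) from None
    sums = metrics.groupby(group_col, sort=False)[metric_col].sum()
    grand = float(sums.sum())
    if grand <= 0:
        raise AmuError("share_of_total: grand total is zero")
    df = pd.DataFrame(
        {
            "group": sums.index,
            "metric": metric,
            "value": sums.values,
            "pct_of_total": [_pct(v, grand) for v in sums.values],
        }
    )
    return (
        df.sort_values(["value", "group"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )


# -- WHO categorization ----------------------------------------------------

def _cia(frame: pd.DataFrame) -> pd.DataFrame:
    total = len(frame)
    per_ind_total = {
        i: int((frame["indication"] == i).sum()) for i in INDICATIONS
    }
    rows = []
    categories = [c.value for c in WhoCategory] + ["CIA_TOTAL"]
    cia_values = [c.value for c in WhoCategory if c.is_cia]
    for name in categories:
        if name == "CIA_TOTAL":
            mask = frame["who_category"].isin(cia_values)
        else:
            mask = frame["who_category"] == name
        row = {
            "who_category": name,
            "n_products": int(mask.sum()),
            "pct_products": _pct(int(mask.sum()), total),
        }
        for ind in INDICATIONS:
            k = int((mask & (frame["indication"] == ind)).sum())
            row[f"n_{ind.lower()}"] = k
            row[f"pct_{ind.lower()}"] = _pct(k, per_ind_total[ind])
        rows.append(row)
    return pd.DataFrame(rows)


def cia_summary(
    events: list[TreatmentEvent], catalogue: Catalogue
) -> pd.DataFrame:
    """Product counts/shares per WHO importance category, with a CIA total."""
    return _cia(events_frame(events, catalogue))


def cia_from_metrics(metrics: pd.DataFrame) -> pd.DataFrame:
    return _cia(metrics)


# -- cases -----------------------------------------------------------------

def condition_case_summary(events: list[TreatmentEvent]) -> pd.DataFrame:
    """Distinct disease cases per indication (events grouped by case key)."""
    if not events:
        return pd.DataFrame(columns=["indication", "n_cases", "pct_cases"])
    cases: dict[str, str] = {}
    for e in events:
        cases.setdefault(e.case_key, e.indication.value)
    counts = pd.Series(list(cases.values())).value_counts()
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "indication": counts.index,
            "n_cases": counts.values,
            "pct_cases": [_pct(n, total) for n in counts.values],
        }
    )


# -- herd-type contrast ----------------------------------------------------

@dataclass
class HerdTypeComparison:
    """Household vs commercial usage contrast on per-herd summed nADD."""

    per_herd: pd.DataFrame  # herd_id, herd_type, n_add
    per_substance: pd.DataFrame  # substance x herd_type summed nADD
    household_mean: float
    commercial_mean: float
    t_statistic: float
    p_value: float


def herd_type_comparison(
    metrics: pd.DataFrame, herds: list[Herd]
) -> HerdTypeComparison:
    """Welch two-sample test of per-herd total nADD between herd types.

    Enrolled herds without any treatment contribute a zero total (they
    were at risk all the same). Requires >= 2 herds of each type.
    """
    type_of = {h.herd_id: h.herd_type.value for h in herds}
    for t in (HerdType.HOUSEHOLD, HerdType.COMMERCIAL):
        if sum(v == t.value for v in type_of.values()) < 2:
            raise AmuError(
                f"herd_type_comparison: need >= 2 {t.value.lower()} herds"
            )
    totals = metrics.groupby("herd_id")["n_add"].sum()
    per_herd = pd.DataFrame(
        {
            "herd_id": [h.herd_id for h in herds],
            "herd_type": [h.herd_type.value for h in herds],
            "n_add": [float(totals.get(h.herd_id, 0.0)) for h in herds],
        }
    )
    hh = per_herd.loc[per_herd["herd_type"] == "HOUSEHOLD", "n_add"].to_numpy()
    cm = per_herd.loc[per_herd["herd_type"] == "COMMERCIAL", "n_add"].to_numpy()
    if np.isclose(hh.mean(), cm.mean()) and np.isclose(
        np.var(hh) + np.var(cm), 0.0
    ):
        t_stat, p_val = 0.0, 1.0  # identical constant samples: no contrast
    else:
        t_stat, p_val = stats.ttest_ind(cm, hh, equal_var=False)

    sub = metrics.assign(herd_type=metrics["herd_id"].map(type_of))
    per_substance = (
        sub.pivot_table(
            index="substance", columns="herd_type", values="n_add",
            aggfunc="sum", fill_value=0.0,
        )
        .reset_index()
        .rename_axis(None, axis=1)
    )
    return HerdTypeComparison(
        per_herd=per_herd,
        per_substance=per_substance,
        household_mean=float(hh.mean()),
        commercial_mean=float(cm.mean()),
        t_statistic=float(t_stat),
        p_value=float(p_val),
    )


# -- drug use rate ---------------------------------------------------------

def adur_table(
    metrics: pd.DataFrame,
    herds: list[Herd],
    *,
    denominator: str = "pooled",
    period_days: int = 365,
) -> pd.DataFrame:
    """Drug use rate (ADD per 1000 animal-days) per substance.

    ``denominator="pooled"`` uses period_days x total animals across herds;
    ``denominator="herd"`` computes a per-herd rate over the herd's own
    enrolment days and animal count, then reports the mean and median rate
    across herds. Since nADD = mass/ADD, the rate reduces to
    nADD x 1000 / animal-days.
    """
    if denominator not in ("pooled", "herd"):
        raise AmuError(f"unknown ADUR denominator mode {denominator!r}")
    if denominator == "pooled":
        animal_days = period_days * sum(h.n_animals for h in herds)
        sums = metrics.groupby("substance", sort=False)["n_add"].sum()
        return (
            pd.DataFrame(
                {
                    "substance": sums.index,
                    "n_add": sums.values,
                    "adur": sums.values * 1000.0 / animal_days,
                }
            )
            .sort_values(["adur", "substance"], ascending=[False, True],
                         kind="stable")
            .reset_index(drop=True)
        )

    herd_days = pd.Series(
        {h.herd_id: float(h.enrolment_days * h.n_animals) for h in herds}
    )
    per = metrics.pivot_table(
        index="substance", columns="herd_id", values="n_add",
        aggfunc="sum", fill_value=0.0,
    )
    for hid in herd_days.index:
        if hid not in per.columns:
            per[hid] = 0.0
    rates = per[list(herd_days.index)].div(herd_days, axis=1) * 1000.0
    return (
        pd.DataFrame(
            {
                "substance": rates.index,
                "mean_herd_adur": rates.mean(axis=1).values,
                "median_herd_adur": rates.median(axis=1).values,
            }
        )
        .sort_values(["mean_herd_adur", "substance"], ascending=[False, True],
                     kind="stable")
        .reset_index(drop=True)
    )


# -- report set ------------------------------------------------------------

def write_reports(
    out_dir: str | Path,
    *,
    metrics: pd.DataFrame,
    herds: list[Herd],
    events: list[TreatmentEvent] | None = None,
    seed: int | None = None,
    config: dict | None = None,
    adur_denominator: str = "pooled",
    period_days: int = 365,
) -> dict:
    """Write the full report set and a run manifest; returns the manifest.

    All tables derive from the metrics frame (so that re-aggregating a
    stored ``metrics.csv`` reproduces them byte-for-byte); the disease-case
    summary additionally needs the events, and is only written when they
    are provided.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tables: dict[str, pd.DataFrame] = {
        "frequency.csv": frequency_from_metrics(metrics),
        "herd_usage.csv": herd_usage_from_metrics(metrics, herds),
        "cia_summary.csv": cia_from_metrics(metrics),
    }
    if not metrics.empty:
        tables["shares_nadd.csv"] = share_of_total(metrics, "substance", "nADD")
        tables["shares_nuadd.csv"] = share_of_total(metrics, "substance", "nUADD")
        tables["shares_nadd_class.csv"] = share_of_total(metrics, "class", "nADD")
        tables["adur.csv"] = adur_table(
            metrics, herds, denominator=adur_denominator, period_days=period_days
        )
        try:
            cmp = herd_type_comparison(metrics, herds)
            cmp_df = cmp.per_herd.copy()
            cmp_df["t_statistic"] = cmp.t_statistic
            cmp_df["p_value"] = cmp.p_value
            tables["herd_type_comparison.csv"] = cmp_df
        except AmuError:
            pass  # fewer than 2 herds of a type: comparison not defined
    if events is not None:
        tables["condition_cases.csv"] = condition_case_summary(events)
    for name, df in tables.items():
        df.to_csv(out / name, index=False)

    config = dict(config or {})
    manifest = {
        "seed": seed,
        "config": config,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_events": len(events) if events is not None else None,
        "n_herds": len(herds),
        "n_metric_rows": int(len(metrics)),
        "tables": sorted(tables),
        "python": platform.python_version(),
        "pandas": pd.__version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
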