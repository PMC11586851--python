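"""Phenotype derivation: energy-corrected milk, daily-record quality control,
trait summaries and the heifer/cow residual feed intake (RFI) regressions.

RFI is the residual of a linear regression of average dry-matter intake on
energy sinks: for growing heifers, average daily gain (ADG), metabolic body
weight (MBW = BW^0.75) and age, fitted within each feed trial; for lactating
cows, a single regression across the herd with trial (26 levels) and
lactation (2 levels) fixed effects plus DIM, DIM^2, age, age^2, BW, ECM and
the body-weight change over the test period.  Negative RFI = efficient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "compute_ecm",
    "filter_daily_records",
    "summarize_cows",
    "summarize_heifers",
    "fit_heifer_rfi",
    "fit_cow_rfi",
    "QCReport",
]

ECM_COEFS = (0.327, 12.95, 7.2)  # milk, fat, protein yield coefficients
QC_TRAITS = ("bw", "dmi", "ecm")


def compute_ecm(milk_yield, fat_yield, protein_yield):
    """Energy-corrected milk (kg/d).

    ECM = 0.327·MY + 12.95·fat yield + 7.2·protein yield, all in kg.
    Linear in its arguments; negative inputs are rejected.
    """
    my = np.asarray(milk_yield, dtype=float)
    fy = np.asarray(fat_yield, dtype=float)
    py = np.asarray(protein_yield, dtype=float)
    if (my < 0).any() or (fy < 0).any() or (py < 0).any():
        raise ValueError("milk, fat and protein yields must be non-negative")
    out = ECM_COEFS[0] * my + ECM_COEFS[1] * fy + ECM_COEFS[2] * py
    return float(out) if out.ndim == 0 else out


@dataclass
class QCReport:
    """Bookkeeping of the daily-record quality control."""

    animals_removed: dict = field(default_factory=dict)  # id -> reason
    per_animal: dict = field(default_factory=dict)  # id -> {trait: {kept, removed}}
    n_total: int = 0
    n_removed: int = 0

    @property
    def fraction_removed(self) -> float:
        return self.n_removed / self.n_total if self.n_total else 0.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "animals_removed": {str(k): v for k, v in self.animals_removed.items()},
                "per_animal": {str(k): v for k, v in self.per_animal.items()},
                "n_total": self.n_total,
                "n_removed": self.n_removed,
                "fraction_removed": self.fraction_removed,
            },
            indent=2,
        )


def _ols_residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def filter_daily_records(
    daily: pd.DataFrame,
    min_records: int = 30,
    sd_threshold: float = 3.0,
) -> tuple[pd.DataFrame, QCReport]:
    """Quality-control daily cow records.

    Steps, per the standard protocol: (1) drop animals with fewer than
    ``min_records`` daily records of BW, DMI or ECM; (2) per animal and trait
    (BW, DMI, ECM), regress the trait on DIM and flag days whose residual
    deviates from the mean residual by more than ``sd_threshold`` SD;
    (3) flagged days where the DMI and milk-yield residuals *both* exceed the
    threshold in the same direction are retained (obvious biological events,
    not measurement errors); (4) everything else flagged is removed per
    trait.  An animal/trait with zero residual variance gets no removals.

    Returns the daily table with boolean ``keep_bw/keep_dmi/keep_ecm``
    columns (removed animals dropped entirely) and a :class:`QCReport`.
    """
    df = daily.copy()
    if "ecm" not in df.columns:
        fy = df["fat_pct"] * df["my"] / 100.0
        py = df["prot_pct"] * df["my"] / 100.0
        df["ecm"] = compute_ecm(df["my"].to_numpy(), fy.to_numpy(), py.to_numpy())

    report = QCReport()
    keep_animals = []
    for animal, sub in df.groupby("animal_id", sort=False):
        counts = {t: int(sub[t].notna().sum()) for t in QC_TRAITS}
        short = [t for t, c in counts.items() if c < min_records]
        if short:
            report.animals_removed[animal] = (
                f"fewer than {min_records} daily records for {', '.join(short)}"
            )
        else:
            keep_animals.append(animal)
    df = df[df["animal_id"].isin(keep_animals)].copy()

    for t in QC_TRAITS:
        df[f"keep_{t}"] = True
    n_total = 0
    n_removed = 0
    for animal, sub in df.groupby("animal_id", sort=False):
        dim = sub["dim"].to_numpy(dtype=float)
        flags = {}
        for t in QC_TRAITS + ("my",):
            r = _ols_residuals(sub[t].to_numpy(dtype=float), dim)
            sd = r.std(ddof=1)
            if sd == 0:
                flags[t] = (np.zeros(len(r), dtype=bool), np.zeros(len(r)))
            else:
                z = (r - r.mean()) / sd
                flags[t] = (np.abs(z) > sd_threshold, z)
        # biological exception: same-direction DMI and MY excursions are kept
        dmi_f, dmi_z = flags["dmi"]
        my_f, my_z = flags["my"]
        protected = dmi_f & my_f & (np.sign(dmi_z) == np.sign(my_z))
        stats = {}
        for t in QC_TRAITS:
            f, _ = flags[t]
            remove = f & ~protected
            df.loc[sub.index, f"keep_{t}"] = ~remove
            stats[t] = {"kept": int((~remove).sum()), "removed": int(remove.sum())}
            n_total += len(remove)
            n_removed += int(remove.sum())
        report.per_animal[animal] = stats
    report.n_total = n_total
    report.n_removed = n_removed
    return df, report


def summarize_cows(
    filtered: pd.DataFrame, delta_bw_mode: str = "fitted"
) -> pd.DataFrame:
    """Collapse QC'd daily records to one trait record per cow.

    Trait averages are means over that trait's kept days.  ΔBW is the change
    in body weight over the test period: in ``fitted`` mode (default) the
    per-animal OLS line of BW on DIM evaluated at the last minus the first
    kept day (robust to single-day noise); in ``raw`` mode the raw last minus
    first kept BW record.  avg_dim and avg_age are means over kept DMI days.
    """
    if delta_bw_mode not in ("fitted", "raw"):
        raise ValueError("delta_bw_mode must be 'fitted' or 'raw'")
    rows = []
    for animal, sub in filtered.groupby("animal_id", sort=False):
        bw = sub[sub["keep_bw"]]
        dmi = sub[sub["keep_dmi"]]
        ecm = sub[sub["keep_ecm"]]
        dim = bw["dim"].to_numpy(dtype=float)
        y = bw["bw"].to_numpy(dtype=float)
        X = np.column_stack([np.ones_like(dim), dim])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        if delta_bw_mode == "fitted":
            delta_bw = float(beta[1] * (dim.max() - dim.min()))
        else:
            delta_bw = float(y[np.argmax(dim)] - y[np.argmin(dim)])
        rows.append(
            {
                "animal_id": animal,
                "trial": sub["trial"].iloc[0],
                "lactation": sub["lactation"].iloc[0],
                "avg_dmi": float(dmi["dmi"].mean()),
                "avg_bw": float(y.mean()),
                "avg_ecm": float(ecm["ecm"].mean()),
                "delta_bw": delta_bw,
                "avg_dim": float(dmi["dim"].mean()),
                "avg_age": float(dmi["age"].mean()),
                "n_bw": len(bw),
                "n_dmi": len(dmi),
                "n_ecm": len(ecm),
            }
        )
    return pd.DataFrame(rows)


def summarize_heifers(
    serial_bw: pd.DataFrame,
    daily_dmi: pd.DataFrame,
    meta: pd.DataFrame,
    mbw_exponent: float = 0.75,
) -> pd.DataFrame:
    """Collapse heifer trial data to one test record per heifer.

    ADG is the OLS slope of the serial body weights on trial day (at least
    two weighings required); MBW is the mean of the observed BW raised to
    ``mbw_exponent`` (0.75 = standard metabolic body weight); avg_dmi is the
    mean daily intake.
    """
    meta_idx = meta.set_index("animal_id")
    rows = []
    for animal, sub in serial_bw.groupby("animal_id", sort=False):
        day = sub["day"].to_numpy(dtype=float)
        bw = sub["bw"].to_numpy(dtype=float)
        if len(np.unique(day)) < 2:
            raise ValueError(
                f"animal {animal}: ADG slope undefined with a single BW point"
            )
        X = np.column_stack([np.ones_like(day), day])
        beta, *_ = np.linalg.lstsq(X, bw, rcond=None)
        dmi = daily_dmi.loc[daily_dmi["animal_id"] == animal, "dmi"]
        rows.append(
            {
                "animal_id": animal,
                "trial": meta_idx.loc[animal, "trial"],
                "avg_dmi": float(dmi.mean()),
                "mbw": float(np.mean(bw**mbw_exponent)),
                "adg": float(beta[1]),
                "avg_age": float(meta_idx.loc[animal, "age"]),
            }
        )
    return pd.DataFrame(rows)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns involved in the deficiency
        bad = []
        keep: list[int] = []
        for j in range(X.shape[1]):
            cand = keep + [j]
            if np.linalg.matrix_rank(X[:, cand]) == len(keep):
                bad.append(names[j])
            else:
                keep.append(j)
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")


def fit_heifer_rfi(
    records: pd.DataFrame, min_per_trial: int = 5
) -> tuple[pd.Series, pd.DataFrame]:
    """Heifer RFI: within each trial, OLS of avg_dmi on ADG, MBW and age;
    the residual is RFI_heifer.  Returns (rfi series indexed by animal_id,
    per-trial coefficient table)."""
    rfi = {}
    coefs = []
    for trial, sub in records.groupby("trial", sort=False):
        if len(sub) < min_per_trial:
            raise ValueError(
                f"trial {trial} has {len(sub)} animals; need >= {min_per_trial}"
            )
        X = np.column_stack(
            [
                np.ones(len(sub)),
                sub["adg"].to_numpy(dtype=float),
                sub["mbw"].to_numpy(dtype=float),
                sub["avg_age"].to_numpy(dtype=float),
            ]
        )
        _check_rank(X, ["intercept", "adg", "mbw", "avg_age"])
        y = sub["avg_dmi"].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        for a, r in zip(sub["animal_id"], resid):
            rfi[a] = float(r)
        coefs.append(
            {"trial": trial, "mu": beta[0], "b_adg": beta[1], "b_mbw": beta[2], "b_age": beta[3]}
        )
    return pd.Series(rfi, name="rfi_heifer"), pd.DataFrame(coefs)


def fit_cow_rfi(records: pd.DataFrame, min_per_level: int = 2):
    """Cow RFI: one OLS across all cows of avg_dmi on trial (fixed), lactation
    (fixed), DIM, DIM^2, age, age^2, BW, ECM and ΔBW; the residual is
    RFI_cow.  When an animal has records from both lactations, only the
    first-lactation record is used.  Returns (rfi series indexed by
    animal_id, fitted statsmodels results)."""
    import statsmodels.formula.api as smf

    df = records.copy()
    df = df.sort_values(["animal_id", "lactation"], kind="stable")
    df = df.drop_duplicates(subset="animal_id", keep="first").reset_index(drop=True)

    for col, lab in (("trial", "trial"), ("lactation", "lactation")):
        counts = df[col].value_counts()
        if (counts < min_per_level).any() and counts.size > 1:
            small = counts[counts < min_per_level].index.tolist()
            raise ValueError(f"{lab} level(s) {small} have < {min_per_level} animals")

    df["dim2"] = df["avg_dim"] ** 2
    df["age2"] = df["avg_age"] ** 2
    terms = ["avg_dim", "dim2", "avg_age", "age2", "avg_bw", "avg_ecm", "delta_bw"]
    formula = "avg_dmi ~ " + " + ".join(terms)
    if df["trial"].nunique() > 1:
        formula += " + C(trial)"
    if df["lactation"].nunique() > 1:
        formula += " + C(lactation)"
    model = smf.ols(formula, data=df)
    X = model.exog
    _check_rank(X, list(model.exog_names))
    res = model.fit()
    rfi = pd.Series(
        res.resid.to_numpy(), index=df["animal_id"].to_numpy(), name="rfi_cow"
    )
    return rfi, res
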