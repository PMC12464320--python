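"""Resistance profiles: from droplet counts to normalized growth fractions.

For each antibiotic concentration c on the tested grid a sample yields the
total droplet count N(c) and the number of growth-positive droplets N+(c).
The positive fraction f+(c) = N+(c)/N(c), normalized to the antibiotic-free
control, gives the resistance profile F_R(c) = f+(c)/f+(0): the fraction of
individually encapsulated cells still proliferating at concentration c.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "ResistanceProfile",
    "positive_fraction",
    "normalize",
    "average_replicates",
    "build_profile",
]


@dataclass
class CountTable:
    """Per-concentration droplet counts for one replicate.

    ``data`` has columns ``concentration``, ``n_total``, ``n_positive``
    sorted by concentration; the grid must include c = 0 (the no-antibiotic
    control the profile is normalized to).
    """

    replicate_id: str
    data: pd.DataFrame
    unit: str = ""

    def __post_init__(self):
        required = {"concentration", "n_total", "n_positive"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"count table missing columns: {sorted(missing)}")
        df = self.data.loc[:, ["concentration", "n_total", "n_positive"]].copy()
        df = df.sort_values("concentration").reset_index(drop=True)
        if df["concentration"].duplicated().any():
            dups = df.loc[df["concentration"].duplicated(), "concentration"].tolist()
            raise ValueError(f"duplicate concentrations in replicate "
                             f"{self.replicate_id!r}: {dups}")
        if (df["concentration"] < 0).any():
            raise ValueError("concentrations must be >= 0")
        if df["concentration"].iloc[0] != 0:
            raise ValueError("concentration grid must include c = 0")
        if (df["n_total"] < 0).any() or (df["n_positive"] < 0).any():
            raise ValueError("counts must be non-negative")
        if (df["n_positive"] > df["n_total"]).any():
            bad = df.loc[df["n_positive"] > df["n_total"], "concentration"].tolist()
            raise ValueError(f"n_positive > n_total at concentrations {bad}")
        self.data = df

    @property
    def concentrations(self) -> np.ndarray:
        return self.data["concentration"].to_numpy(dtype=float)


@dataclass
class ResistanceProfile:
    """Normalized proliferating fraction F_R(c) on a concentration grid."""

    concentration: np.ndarray
    f_plus: np.ndarray
    f_r: np.ndarray
    n_replicates: int = 1
    f_r_sd: np.ndarray | None = None  # per-point SD across replicates
    unit: str = ""
    sample: str = ""

    def __post_init__(self):
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.f_plus = np.asarray(self.f_plus, dtype=float)
        self.f_r = np.asarray(self.f_r, dtype=float)
        if not (len(self.concentration) == len(self.f_plus) == len(self.f_r)):
            raise ValueError("concentration, f_plus and f_r must be equally long")
        if self.f_r_sd is not None:
            self.f_r_sd = np.asarray(self.f_r_sd, dtype=float)
            if len(self.f_r_sd) != len(self.concentration):
                raise ValueError("f_r_sd length mismatch")
            if np.any(self.f_r_sd < 0):
                raise ValueError("per-point SD must be >= 0")
        if np.any(self.f_r < 0):
            raise ValueError("F_R values must be >= 0")
        if self.concentration[0] != 0 or not np.isclose(self.f_r[0], 1.0):
            raise ValueError("profile must start at c = 0 with F_R(0) = 1")


def positive_fraction(table: CountTable) -> pd.Series:
    """f+(c) = N+(c)/N(c) per concentration, as a Series indexed by c."""
    zero_total = table.data["n_total"] == 0
    if zero_total.any():
        concs = table.data.loc[zero_total, "concentration"].tolist()
        raise ValueError(
            f"n_total is 0 at concentration(s) {concs} in replicate "
            f"{table.replicate_id!r}; positive fraction undefined"
        )
    s = table.data["n_positive"] / table.data["n_total"]
    s.index = pd.Index(table.data["concentration"], name="concentration")
    return s.rename("f_plus")


def normalize(f_plus: pd.Series) -> pd.Series:
    """F_R(c) = f+(c)/f+(0).  Values above 1 are retained, never clipped."""
    if 0 not in f_plus.index:
        raise ValueError("f_plus must contain the c = 0 control point")
    f0 = float(f_plus.loc[0])
    if f0 <= 0:
        raise ValueError(
            "f_plus(0) = 0: no growth in the antibiotic-free control; "
            "the resistance profile is undefined"
        )
    return (f_plus / f0).rename("F_R")


def average_replicates(tables: list[CountTable]) -> CountTable:
    """Average raw counts across replicates on a shared concentration grid.

    Returns a (fractional-count) table of mean N(c) and mean N+(c); the
    profile is then computed from the averaged counts, matching the
    average-then-normalize convention used for fitting.
    """
    if not tables:
        raise ValueError("no replicates given")
    grids = [tuple(t.data["concentration"]) for t in tables]
    ref = set(grids[0])
    for t, g in zip(tables[1:], grids[1:]):
        if tuple(sorted(ref)) != tuple(sorted(set(g))) or len(g) != len(grids[0]):
            missing = sorted(ref.symmetric_difference(g))
            raise ValueError(
                f"replicate {t.replicate_id!r} grid mismatch; differing "
                f"concentrations: {missing}"
            )
    conc = np.asarray(grids[0], dtype=float)
    n_tot = np.mean([t.data["n_total"].to_numpy(dtype=float) for t in tables], axis=0)
    n_pos = np.mean([t.data["n_positive"].to_numpy(dtype=float) for t in tables], axis=0)
    return CountTable(
        replicate_id="mean",
        data=pd.DataFrame(
            {"concentration": conc, "n_total": n_tot, "n_positive": n_pos}
        ),
        unit=tables[0].unit,
    )


def build_profile(
    tables: list[CountTable],
    method: str = "average_counts",
    sample: str = "",
) -> ResistanceProfile:
    """Replicate count tables -> ResistanceProfile.

    ``method='average_counts'`` (default) averages raw N and N+ across
    replicates first and normalizes once; ``'per_replicate'`` normalizes each
    replicate by its own control and averages the per-replicate F_R curves
    (sensitivity-analysis alternative).  Per-point SD across the replicate
    F_R curves is retained either way (``None`` for a single replicate).
    """
    if not tables:
        raise ValueError("no replicates given")
    per_rep = [normalize(positive_fraction(t)) for t in tables]
    fr_matrix = np.vstack([s.to_numpy(dtype=float) for s in per_rep])
    sd = fr_matrix.std(axis=0, ddof=1) if len(tables) > 1 else None

    if method == "average_counts":
        mean_table = average_replicates(tables)
        f_plus = positive_fraction(mean_table)
        f_r = normalize(f_plus)
    elif method == "per_replicate":
        mean_table = average_replicates(tables)
        f_plus = positive_fraction(mean_table)
        f_r = pd.Series(
            fr_matrix.mean(axis=0), index=f_plus.index, name="F_R"
        )
    else:
        raise ValueError("method must be 'average_counts' or 'per_replicate'")

    return ResistanceProfile(
        concentration=f_plus.index.to_numpy(dtype=float),
        f_plus=f_plus.to_numpy(dtype=float),
        f_r=f_r.to_numpy(dtype=float),
        n_replicates=len(tables),
        f_r_sd=sd,
        unit=tables[0].unit,
        sample=sample,
    )
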