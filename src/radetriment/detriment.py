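"""Severity weighting and radiation detriment.

The detriment of tissue T is

    D_T = R_T * (k_T + (1 - k_T) * q_T) * L_rel,T = R_T * d_T

with R_T the nominal risk coefficient (per 10,000 persons per Sv), k_T the
lethality factor, q_T = q_min + k_T*(1 - q_min) the loss of quality of life,
and L_rel,T the relative life lost.  The dimensionless inner factor d_T is
the "severity" of the disease; it is independent of radiation and is the
part of the model that drifts as cancer care improves.

Two q sources exist: the pipeline computes q from k via the formula above;
tabulated reproductions may instead supply a printed q (rounded to reporting
precision), which is what the bundled USA-2012 worked example uses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .sites import ICRP103_SITES, CancerSite, usa_2012_reference


def quality_of_life(k, q_min):
    """q = q_min + k*(1 - q_min): quality-of-life loss as a function of lethality.

    Strictly increasing in k; q(0) = q_min, q(1) = 1.  Accepts scalars or
    arrays.
    """
    k = np.asarray(k, dtype=float)
    q_min = np.asarray(q_min, dtype=float)
    if np.any(k < 0) or np.any(k > 1):
        raise DomainError("lethality k must lie in [0, 1]")
    if np.any(q_min < 0) or np.any(q_min >= 1):
        raise DomainError("q_min must lie in [0, 1)")
    out = q_min + k * (1.0 - q_min)
    return float(out) if out.ndim == 0 else out


def severity(k, q, l_rel):
    """d = (k + (1 - k)*q) * L_rel: the radiation-independent damage weight."""
    k = np.asarray(k, dtype=float)
    q = np.asarray(q, dtype=float)
    l_rel = np.asarray(l_rel, dtype=float)
    if np.any(k < 0) or np.any(k > 1) or np.any(q < 0) or np.any(q > 1):
        raise DomainError("k and q must lie in [0, 1]")
    if np.any(l_rel <= 0):
        raise DomainError("relative life lost must be positive")
    out = (k + (1.0 - k) * q) * l_rel
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DetrimentRow:
    """One organ row: lethality, quality of life, life lost, severity, detriment."""

    site: CancerSite
    k: float
    q: float
    l_rel: float
    severity: float
    detriment: float  # per 10,000 persons per Sv


@dataclass(frozen=True)
class DetrimentTable:
    """Per-organ detriment rows plus their total for one evaluation."""

    rows: tuple[DetrimentRow, ...]
    year: int | None = None

    @property
    def total(self) -> float:
        """Total detriment, cases per 10,000 persons per Sv."""
        return float(sum(r.detriment for r in self.rows))

    @property
    def total_percent_per_sv(self) -> float:
        """Total detriment expressed as % per Sv."""
        return self.total / 100.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": [r.site.name for r in self.rows],
                "icd10": [r.site.icd10 for r in self.rows],
                "risk_per_10k_sv": [r.site.risk for r in self.rows],
                "k": [r.k for r in self.rows],
                "q": [r.q for r in self.rows],
                "l_rel": [r.l_rel for r in self.rows],
                "severity": [r.severity for r in self.rows],
                "detriment_per_10k_sv": [r.detriment for r in self.rows],
            }
        ).set_index("site")

    def summary(self) -> str:
        """Rounded report: detriments at 1 dp, factors at 2 dp."""
        df = self.to_frame()
        lines = [
            f"{'site':<12}{'ICD-10':<10}{'R':>7}{'k':>8}{'q':>8}{'L_rel':>8}{'D':>9}"
        ]
        for site, row in df.iterrows():
            icd = row["icd10"] if row["icd10"] is not None else "-"
            lines.append(
                f"{site:<12}{icd:<10}{row['risk_per_10k_sv']:>7.0f}"
                f"{row['k']:>8.2f}{row['q']:>8.2f}{row['l_rel']:>8.2f}"
                f"{row['detriment_per_10k_sv']:>9.1f}"
            )
        lines.append(f"{'total detriment':<35}{'':>17}{self.total:>9.1f}")
        lines.append(f"total detriment: {self.total_percent_per_sv:.2f} % per Sv")
        return "\n".join(lines)


def detriment_row(
    site: CancerSite,
    k: float | None = None,
    l_rel: float | None = None,
    q_override: float | None = None,
) -> DetrimentRow:
    """Evaluate one organ row; fixed sites bypass to their frozen values.

    For computed sites, q defaults to the formula q(k, q_min); passing
    ``q_override`` reproduces tabulations where q was rounded before D.
    """
    if site.fixed:
        return DetrimentRow(
            site, site.k, site.q, site.l_rel,
            site.detriment / site.risk, site.detriment,
        )
    if k is None or l_rel is None:
        raise DomainError(f"computed site {site.name!r} needs k and l_rel")
    q = quality_of_life(k, site.q_min) if q_override is None else float(q_override)
    d = severity(k, q, l_rel)
    return DetrimentRow(site, float(k), q, float(l_rel), d, site.risk * d)


def total_detriment(
    rows: Iterable[DetrimentRow],
    year: int | None = None,
    expected_sites: Sequence[CancerSite] | None = None,
) -> DetrimentTable:
    """Sum organ rows into a table; each configured site exactly once."""
    rows = tuple(rows)
    names = [r.site.name for r in rows]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise DomainError(f"duplicated site rows: {dupes}")
    if expected_sites is not None:
        expected = {s.name for s in expected_sites}
        missing = expected - set(names)
        extra = set(names) - expected
        if missing or extra:
            raise DomainError(
                f"site mismatch: missing {sorted(missing)}, unexpected {sorted(extra)}"
            )
    return DetrimentTable(rows, year)


def usa_2012_detriment_table(q_source: str = "printed") -> DetrimentTable:
    """The bundled USA-2012 worked example of the full detriment table.

    ``q_source="printed"`` (default) evaluates D from the tabulated
    2-decimal q values, matching the reference table's own rounding;
    ``"computed"`` re-derives q from k instead.
    """
    if q_source not in ("printed", "computed"):
        raise DomainError(f"unknown q source {q_source!r}")
    ref = usa_2012_reference()
    rows = []
    for site in ICRP103_SITES:
        if site.fixed:
            rows.append(detriment_row(site))
            continue
        r = ref.loc[site.name]
        rows.append(
            detriment_row(
                site,
                k=float(r["k"]),
                l_rel=float(r["l_rel"]),
                q_override=float(r["q"]) if q_source == "printed" else None,
            )
        )
    return total_detriment(rows, year=2012, expected_sites=ICRP103_SITES)


# -- functional views of the severity term ----------------------------------

def severity_curve(k, q_min: float, l_rel: float = 1.0):
    """d(k) and its non-lethal part Δd(k) = d(k) - k·L_rel on given k values.

    With L_rel = 1: d(0) = q_min, d(1) = 1, and Δd vanishes at k = 1.
    """
    k = np.asarray(k, dtype=float)
    d = severity(k, quality_of_life(k, q_min), l_rel)
    return d, d - k * l_rel


def delta_severity_argmax(q_min: float) -> float:
    """Lethality at which the non-lethal part Δd(k) peaks (L_rel = 1).

    Δd = (1-k)(q_min + k(1-q_min)) is quadratic in k with maximum at
    k* = (1 - 2 q_min) / (2 (1 - q_min)); 4/9 for the default q_min = 0.1.
    """
    if not 0.0 <= q_min < 1.0:
        raise DomainError("q_min must lie in [0, 1)")
    return max(0.0, (1.0 - 2.0 * q_min) / (2.0 * (1.0 - q_min)))


def detriment_vs_common_lethality(
    k,
    sites: Sequence[CancerSite] | None = None,
    l_rel: dict[str, float] | None = None,
    include_skin: bool = True,
    uniform_q_min: float | None = None,
):
    """Total detriment D(k) when every computed site shares one lethality k.

    Each non-fixed site keeps its own R_T, q_min (unless ``uniform_q_min``)
    and L_rel,T; fixed rows contribute their frozen detriments unchanged.
    ``l_rel`` maps site name -> relative life lost (defaults to the USA-2012
    worked-example values).  Monotone non-decreasing in k.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 0) or np.any(k > 1):
        raise DomainError("lethality k must lie in [0, 1]")
    sites = list(sites) if sites is not None else list(ICRP103_SITES)
    if l_rel is None:
        ref = usa_2012_reference()
        l_rel = {name: float(ref.loc[name, "l_rel"]) for name in ref.index}
    total = np.zeros_like(k, dtype=float)
    for site in sites:
        if site.fixed:
            total = total + site.detriment
            continue
        if site.name == "skin" and not include_skin:
            continue
        q_min = site.q_min if uniform_q_min is None else uniform_q_min
        d, _ = severity_curve(k, q_min, l_rel[site.name])
        total = total + site.risk * d
    return float(total) if total.ndim == 0 else total
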