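"""Cancer-site catalogue: ICRP 103 nominal risk coefficients and q_min rules.

Fourteen organs/tissues enter the total detriment.  Twelve are "computed"
sites whose lethality and life lost come from registry data; two are fixed
rows — gonads (heritable effects) and the "other solid cancers" remainder —
whose severity components are taken verbatim from ICRP 103 and held constant
in time.

The minimum quality-of-life loss ``q_min`` follows the ICRP rules: 0 for
skin, 0.2 for thyroid, 0.1 for every other site.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .exceptions import ConfigError


@dataclass(frozen=True)
class CancerSite:
    """One organ/tissue row of the detriment model.

    ``risk`` is the nominal risk coefficient R_T in cases per 10,000 persons
    per Sv.  Fixed sites carry frozen (k, q, l_rel, detriment) used verbatim;
    computed sites carry ``None`` there.
    """

    name: str
    icd10: str | None
    risk: float
    q_min: float
    fixed: bool = False
    k: float | None = None
    q: float | None = None
    l_rel: float | None = None
    detriment: float | None = None

    def __post_init__(self) -> None:
        if self.risk <= 0:
            raise ConfigError(f"site {self.name!r}: risk coefficient must be positive")
        if not 0.0 <= self.q_min < 1.0:
            raise ConfigError(f"site {self.name!r}: q_min must lie in [0, 1)")
        if self.fixed and None in (self.k, self.q, self.l_rel, self.detriment):
            raise ConfigError(
                f"fixed site {self.name!r} must carry frozen k, q, l_rel and detriment"
            )


def _read_bundled(filename: str) -> pd.DataFrame:
    with resources.files("radetriment.data").joinpath(filename).open("r") as fh:
        return pd.read_csv(fh)


def load_sites() -> list[CancerSite]:
    """The 14-site ICRP 103 catalogue from the bundled constants file."""
    df = _read_bundled("icrp103_sites.csv")
    out = []
    for row in df.itertuples(index=False):
        fixed = bool(row.fixed)
        out.append(
            CancerSite(
                name=row.name,
                icd10=None if pd.isna(row.icd10) else row.icd10,
                risk=float(row.risk_per_10k_sv),
                q_min=float(row.q_min),
                fixed=fixed,
                k=float(row.k) if fixed else None,
                q=float(row.q) if fixed else None,
                l_rel=float(row.l_rel) if fixed else None,
                detriment=float(row.detriment) if fixed else None,
            )
        )
    return out


def usa_2012_reference() -> pd.DataFrame:
    """Worked-example inputs: USA 2012 lethality, quality of life, relative
    life lost and per-site detriment for the 12 computed sites, as printed
    at 2-decimal reporting precision."""
    return _read_bundled("usa2012_reference.csv").set_index("name")


#: Module-level catalogue; treat as read-only.
ICRP103_SITES: list[CancerSite] = load_sites()

SITE_BY_NAME: dict[str, CancerSite] = {s.name: s for s in ICRP103_SITES}

COMPUTED_SITES: list[CancerSite] = [s for s in ICRP103_SITES if not s.fixed]
FIXED_SITES: list[CancerSite] = [s for s in ICRP103_SITES if s.fixed]
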