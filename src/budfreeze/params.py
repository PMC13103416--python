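"""Cultivar x percentile parameter table for the cold-hardiness engine.

Parameters ship as a long-format CSV (``cultivar``, ``percentile``,
``param_name``, ``value``, ``source``) so an alternative transcription can be
dropped in without code changes.  The packaged defaults reproduce the
documented qualitative behavior of the three parameterized cultivars
(Cabernet-Sauvignon the least hardy with slow deacclimation, Riesling
intermediate, Concord the hardiest with fast deacclimation).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from importlib import resources

import pandas as pd

from .errors import ParameterError

CULTIVARS = ("Cabernet-Sauvignon", "Riesling", "Concord")
PERCENTILES = (10, 50, 90)


@dataclass(frozen=True)
class CultivarParams:
    """One cultivar/percentile parameter vector.

    Cold hardiness is on the lethal-temperature scale (more negative =
    hardier); ``ch_max_c`` is the most negative value attainable.
    """

    cultivar: str
    percentile: int
    ch_max_c: float          # maximum-hardiness bound (< 0)
    ch_init_c: float         # hardiness at integration start
    acc_rate: float          # acclimation gain per degree of driving force
    acc_temp_max_c: float    # warmest temp eliciting acclimation at zero chill
    acc_chill_decay: float   # decline of that ceiling per chill portion
    dea_rate: float          # deacclimation rate per degree above base
    dea_temp_base_c: float   # base temperature for deacclimation response
    pot_chill_half: float    # chill portions at half deacclimation potential
    pot_steepness: float     # logistic steepness of the potential

    def __post_init__(self) -> None:
        if self.ch_max_c >= 0.0:
            raise ParameterError(
                f"{self.cultivar}/{self.percentile}: ch_max_c must be < 0"
            )
        if self.percentile not in PERCENTILES:
            raise ParameterError(f"percentile {self.percentile} not in 10/50/90")


PARAM_NAMES = tuple(
    f.name for f in fields(CultivarParams) if f.name not in ("cultivar", "percentile")
)


def load_params(path=None) -> dict[tuple[str, int], CultivarParams]:
    """Load the full parameter table, keyed by (cultivar, percentile).

    With ``path=None`` the packaged defaults are used.  The table must be
    fully populated: three cultivars x three percentiles x all parameters.
    """
    if path is None:
        with resources.files("budfreeze.data").joinpath(
            "cultivar_params.csv"
        ).open() as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(path)
    out: dict[tuple[str, int], CultivarParams] = {}
    for (cultivar, percentile), grp in table.groupby(["cultivar", "percentile"]):
        vals = dict(zip(grp["param_name"], grp["value"].astype(float)))
        missing = set(PARAM_NAMES) - set(vals)
        if missing:
            raise ParameterError(
                f"{cultivar}/{percentile}: missing parameters {sorted(missing)}"
            )
        extra = set(vals) - set(PARAM_NAMES)
        if extra:
            raise ParameterError(
                f"{cultivar}/{percentile}: unknown parameters {sorted(extra)}"
            )
        out[(str(cultivar), int(percentile))] = CultivarParams(
            cultivar=str(cultivar), percentile=int(percentile), **vals
        )
    for cultivar in CULTIVARS:
        for percentile in PERCENTILES:
            if (cultivar, percentile) not in out:
                raise ParameterError(
                    f"parameter table incomplete: no {cultivar}/{percentile}"
                )
    return out


_DEFAULTS: dict[tuple[str, int], CultivarParams] | None = None


def default_params() -> dict[tuple[str, int], CultivarParams]:
    """Packaged parameter table (cached)."""
    global _DEFAULTS
    if _DEFAULTS is None:
        _DEFAULTS = load_params()
    return _DEFAULTS


def params_for(cultivar: str, percentile: int,
               table: dict[tuple[str, int], CultivarParams] | None = None
               ) -> CultivarParams:
    table = table if table is not None else default_params()
    try:
        return table[(cultivar, percentile)]
    except KeyError:
        raise ParameterError(
            f"no parameters for cultivar={cultivar!r} percentile={percentile}"
        ) from None
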