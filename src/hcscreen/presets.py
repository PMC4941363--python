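"""Ready-made simulation scenarios mirroring the screening study designs.

Each preset encodes one experimental design as generative truth:

* ``dht-agonist`` — six-point agonist dose response, 10 pM to 100 nM,
  raising receptor nuclear level and nuclear/cytoplasmic ratio.
* ``bpap-dose-response`` — six-point down-regulator dose response spanning
  1.25-40 uM with a 15 uM midpoint on nuclear level, an S-phase fraction
  falling from 0.27 to 0.04 and a 60% cell-number loss at saturation.
* ``edu-demo`` — vehicle (27% S phase) vs saturating treatment (4%).
* ``mito-demo`` — mitochondria puncta with halved intensity and reduced
  size under treatment.
* ``jc1-demo`` — JC-1 red/green fields with a depolarising CCCP control.
* ``demo-screen`` — two cell-line configs x eight compounds at 10 uM, each
  alone and with 1 nM agonist, plus vehicle/agonist controls; one
  engineered down-regulator ("BPAP") acts only in the variant-expressing
  line, emulating a cell-line-specific hit.

Cell densities per field and intensity scales are free parameters of the
generator (documented in the config defaults), chosen so a 400x400 px
field holds ~50 well-separated cells.
"""
from __future__ import annotations

import numpy as np

from .simulate import BiologConfig, Condition, EffectModel, PlateSimConfig

__all__ = ["make_preset", "PRESETS", "demo_screen_configs", "biolog_preset"]

BPAP_DOSES_UM = [1.25, 2.5, 5.0, 10.0, 20.0, 40.0]
DHT_DOSES_NM = list(np.round(np.logspace(-2, 2, 6), 4))  # 10 pM .. 100 nM

_BPAP_LEVEL = EffectModel(top=1000.0, bottom=400.0, ec50=15.0, hill_slope=1.2)
_BPAP_SPHASE = EffectModel(top=0.27, bottom=0.04, ec50=15.0, hill_slope=1.2)
_BPAP_DENSITY = EffectModel(top=1.0, bottom=0.4, ec50=15.0, hill_slope=1.2)
_DHT_LEVEL = EffectModel(
    top=1400.0, bottom=700.0, ec50=0.3, hill_slope=1.0, direction="up"
)
_DHT_RATIO = EffectModel(
    top=3.5, bottom=1.5, ec50=0.3, hill_slope=1.0, direction="up"
)


def _vehicle(**kw) -> Condition:
    return Condition(compound="vehicle", dose=0.0, **kw)


def _dht_control() -> Condition:
    return Condition(
        compound="DHT",
        dose=1.0,
        dose_unit="nM",
        effect=_DHT_LEVEL,
        ratio_effect=_DHT_RATIO,
    )


def dht_dose_response(seed: int = 0) -> PlateSimConfig:
    conds = {"vehicle": _vehicle()}
    for d in DHT_DOSES_NM:
        conds[f"DHT_{d}nM"] = Condition(
            compound="DHT",
            dose=float(d),
            dose_unit="nM",
            effect=_DHT_LEVEL,
            ratio_effect=_DHT_RATIO,
        )
    return PlateSimConfig(conditions=conds, seed=seed)


def bpap_dose_response(seed: int = 0) -> PlateSimConfig:
    conds = {"vehicle": _vehicle(), "DHT_1nM": _dht_control()}
    for d in BPAP_DOSES_UM:
        conds[f"BPAP_{d}uM"] = Condition(
            compound="BPAP",
            dose=float(d),
            effect=_BPAP_LEVEL,
            s_phase_effect=_BPAP_SPHASE,
            density_effect=_BPAP_DENSITY,
        )
    return PlateSimConfig(conditions=conds, seed=seed)


def edu_demo(seed: int = 0) -> PlateSimConfig:
    conds = {
        "vehicle": _vehicle(s_phase_fraction=0.27),
        "BPAP_20uM": Condition(
            compound="BPAP", dose=20.0, effect=_BPAP_LEVEL, s_phase_fraction=0.04
        ),
    }
    return PlateSimConfig(
        conditions=conds,
        channels=("dapi", "receptor", "edu"),
        cells_per_field=60,
        seed=seed,
    )


def mito_demo(seed: int = 0) -> PlateSimConfig:
    conds = {
        "vehicle": _vehicle(mito_intensity=500.0, mito_radius=2.0),
        "BPAP_20uM": Condition(
            compound="BPAP", dose=20.0, mito_intensity=250.0, mito_radius=1.5
        ),
    }
    return PlateSimConfig(
        conditions=conds,
        channels=("dapi", "mito"),
        cells_per_field=30,
        n_replicates=2,
        seed=seed,
    )


def jc1_demo(seed: int = 0) -> PlateSimConfig:
    conds = {
        "vehicle": _vehicle(jc1_ratio=2.0),
        "BPAP_20uM": Condition(compound="BPAP", dose=20.0, jc1_ratio=1.8),
        "CCCP_50uM": Condition(compound="CCCP", dose=50.0, jc1_ratio=0.4),
    }
    return PlateSimConfig(
        conditions=conds,
        channels=("dapi", "jc1_red", "jc1_green"),
        cells_per_field=30,
        n_replicates=2,
        seed=seed,
    )


_SCREEN_COMPOUNDS = ["BPAP", "BPA", "BPAF", "BPZ", "MDV3100", "Bic", "Nil", "OHF"]
# receptor-level effects in the variant-expressing ("22Rv1-like") line
_SCREEN_EFFECTS_VARIANT = {"BPAP": _BPAP_LEVEL}
# effects in the androgen-dependent ("LNCaP-like") line: agonist-responsive,
# no down-regulation by BPAP
_SCREEN_EFFECTS_SENSITIVE: dict[str, EffectModel] = {}


def screen_plate(cell_line: str = "22Rv1-like", seed: int = 0) -> PlateSimConfig:
    """Single-dose (10 uM) compound screen +/- 1 nM agonist for one line."""
    variant = "22Rv1" in cell_line or "variant" in cell_line
    effects = _SCREEN_EFFECTS_VARIANT if variant else _SCREEN_EFFECTS_SENSITIVE
    agonist_boost = 1.05 if variant else 1.4  # variant lines barely respond
    conds = {"vehicle": _vehicle(), "DHT_1nM": Condition(
        compound="DHT", dose=1.0, dose_unit="nM",
        effect=EffectModel(top=1000.0 * agonist_boost, bottom=1000.0,
                           ec50=0.3, hill_slope=1.0, direction="up"),
    )}
    for cmpd in _SCREEN_COMPOUNDS:
        eff = effects.get(cmpd)
        conds[cmpd] = Condition(compound=cmpd, dose=10.0, effect=eff)
        # a compound without its own effect leaves the agonist-stimulated
        # level untouched in the combo arm
        conds[f"{cmpd}+DHT"] = Condition(
            compound=cmpd,
            dose=10.0,
            with_agonist=True,
            effect=eff,
            baseline_level=None if eff is not None else 1000.0 * agonist_boost,
        )
    return PlateSimConfig(
        conditions=conds,
        n_replicates=2,
        cells_per_field=40,
        seed=seed,
    )


def demo_screen_configs(seed: int = 0) -> dict[str, PlateSimConfig]:
    """The two-cell-line demo screen used by ``run-all``."""
    return {
        "22Rv1-like": screen_plate("22Rv1-like", seed=seed),
        "LNCaP-like": screen_plate("LNCaP-like", seed=seed + 1),
    }


def biolog_preset(seed: int = 0, n_affected: int = 30, loss: float = 0.5) -> BiologConfig:
    """Phenotype-array scenario: a utilization loss in the treated arm.

    The first ``n_affected`` carbon sources keep only ``loss`` of their
    vehicle utilization under treatment; the rest are unaffected.
    """
    mult = np.ones(90)
    mult[:n_affected] = loss
    return BiologConfig(effect_multipliers=mult, seed=seed)


PRESETS = {
    "dht-agonist": dht_dose_response,
    "bpap-dose-response": bpap_dose_response,
    "edu-demo": edu_demo,
    "mito-demo": mito_demo,
    "jc1-demo": jc1_demo,
    "mini-screen": screen_plate,
}


def make_preset(name: str, seed: int = 0) -> PlateSimConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return PRESETS[name](seed=seed)
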