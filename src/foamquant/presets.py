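"""Generator presets describing foamy-macrophage phenotype populations.

Each :class:`GeneratorPreset` parameterizes one cell population as imaged in a
three-channel high-content assay (nuclear dye / whole-cell cytoplasm dye /
phospholipid dye): cell and nucleus geometry, the per-cell vacuole count and
size distribution, and the mean grey levels of each stained compartment on a
16-bit scale.

The shipped registry covers the conditions of a drug wash-out study on
U937-derived alveolar-like macrophages: untreated controls, amiodarone
(phospholipidosis inducer, 5/10 µM), staurosporine (apoptosis inducer,
0.1/1 µM), fluticasone propionate (10/50 µM) and salbutamol (10/50 µM), each
after a 24 h exposure followed by 0, 24 or 48 h of recovery in drug-free
medium.  Morphometric parameters are transcribed from the reported untreated
baseline (~600 µm² cells, 72 vacuoles/cell occupying 29% of the cell) and the
printed fold-changes per compound; intensities are synthetic but placed so the
standard negative-stain detection threshold of 19,000 grey levels separates
vacuole interiors from stained cytoplasm by far more than 3 standard
deviations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "GeneratorPreset",
    "PresetError",
    "condition_key",
    "get_preset",
    "preset_names",
    "DEFAULT_PRESETS",
    "vacuole_radius_for",
]

#: 16-bit grey-level threshold used by the vacuole detector; presets are
#: validated against it so every planted vacuole is detectable by design.
DETECTION_THRESHOLD = 19_000


class PresetError(ValueError):
    """A preset violates one of its invariants."""


@dataclass(frozen=True)
class GeneratorPreset:
    """Population parameters for one (compound, concentration, time) condition.

    Areas are in µm², lengths in µm, intensities in 16-bit grey levels.
    ``vacuole_count_dispersion`` is the negative-binomial size parameter k
    (variance = mean + mean²/k); ``None`` gives a Poisson count.
    """

    name: str
    cell_area_mean: float
    cell_area_sd: float
    nucleus_area_fraction: float
    vacuole_count_mean: float
    vacuole_count_dispersion: float | None
    vacuole_radius_mean: float
    vacuole_radius_sd: float
    cytoplasm_intensity_mean: float = 30_000.0
    cytoplasm_intensity_sd: float = 1_000.0
    vacuole_interior_intensity_mean: float = 8_000.0
    vacuole_interior_intensity_sd: float = 800.0
    nucleus_intensity_mean: float = 22_000.0
    nucleus_intensity_sd: float = 1_000.0
    phospholipid_intensity_mean: float = 5_000.0
    phospholipid_intensity_sd: float = 500.0
    background_mean: float = 2_000.0
    noise_sd: float = 1_500.0

    def validate(self, detection_threshold: float = DETECTION_THRESHOLD) -> None:
        """Raise :class:`PresetError` naming the first violated invariant."""
        if not (self.cell_area_mean > 0 and self.cell_area_sd >= 0):
            raise PresetError(f"{self.name}: cell area parameters must be positive")
        if not 0.0 < self.nucleus_area_fraction < 1.0:
            raise PresetError(f"{self.name}: nucleus_area_fraction must lie in (0, 1)")
        if self.vacuole_count_mean < 0:
            raise PresetError(f"{self.name}: vacuole_count_mean must be >= 0")
        if self.vacuole_count_dispersion is not None and self.vacuole_count_dispersion <= 0:
            raise PresetError(f"{self.name}: vacuole_count_dispersion must be > 0 or None")
        if self.vacuole_count_mean > 0 and self.vacuole_radius_mean <= 0:
            raise PresetError(f"{self.name}: vacuole_radius_mean must be > 0")
        for attr in (
            "cytoplasm_intensity_mean",
            "vacuole_interior_intensity_mean",
            "nucleus_intensity_mean",
            "phospholipid_intensity_mean",
            "background_mean",
        ):
            value = getattr(self, attr)
            if not 0 <= value <= 65_535:
                raise PresetError(f"{self.name}: {attr}={value} outside [0, 65535]")
        if self.noise_sd < 0:
            raise PresetError(f"{self.name}: noise_sd must be >= 0")
        lo = self.vacuole_interior_intensity_mean + 3 * self.noise_sd
        hi = self.cytoplasm_intensity_mean - 3 * self.noise_sd
        if not lo < detection_threshold < hi:
            raise PresetError(
                f"{self.name}: detection threshold {detection_threshold} not separated "
                f"from vacuole interior / cytoplasm by 3 sigma ({lo:.0f} .. {hi:.0f})"
            )

    def noiseless(self) -> "GeneratorPreset":
        """Copy with every stochastic intensity term zeroed (piecewise-constant render)."""
        return replace(
            self,
            cytoplasm_intensity_sd=0.0,
            vacuole_interior_intensity_sd=0.0,
            nucleus_intensity_sd=0.0,
            phospholipid_intensity_sd=0.0,
            noise_sd=0.0,
        )


def vacuole_radius_for(
    area_fraction: float, count_mean: float, cell_area: float, radius_sd: float
) -> float:
    """Mean vacuole radius (µm) so the expected occupied fraction matches.

    Solves ``count_mean * pi * (mu^2 + sd^2) = area_fraction * cell_area``
    for mu; the expected rasterized vacuole area equals pi r^2 when centers
    are placed at sub-pixel resolution.
    """
    if count_mean <= 0:
        return 0.0
    mean_area = area_fraction * cell_area / count_mean
    mu_sq = mean_area / math.pi - radius_sd**2
    if mu_sq <= 0:
        raise PresetError(
            "radius_sd too large for the requested vacuole area fraction"
        )
    return math.sqrt(mu_sq)


def _make(
    name: str,
    *,
    cell_area: float,
    cell_sd: float = 60.0,
    nucleus_fraction: float = 0.12,
    count: float,
    dispersion: float | None = 60.0,
    fraction: float,
    radius_sd: float = 0.08,
    phos_net: float = 3_000.0,
    **overrides,
) -> GeneratorPreset:
    radius = vacuole_radius_for(fraction, count, cell_area, radius_sd) if count > 0 else 0.3
    preset = GeneratorPreset(
        name=name,
        cell_area_mean=cell_area,
        cell_area_sd=cell_sd,
        nucleus_area_fraction=nucleus_fraction,
        vacuole_count_mean=count,
        vacuole_count_dispersion=dispersion,
        vacuole_radius_mean=radius,
        vacuole_radius_sd=radius_sd if count > 0 else 0.0,
        phospholipid_intensity_mean=2_000.0 + phos_net,
        **overrides,
    )
    preset.validate()
    return preset


def condition_key(compound: str, concentration_uM: float, recovery_h: int) -> tuple:
    """Canonical registry key for a study condition."""
    return (str(compound).lower(), float(concentration_uM), int(recovery_h))


def _untreated(recovery_h: int, *, area, count, fraction) -> tuple:
    key = condition_key("untreated", 0.0, recovery_h)
    return key, _make(
        f"untreated_R{recovery_h}", cell_area=area, count=count, fraction=fraction
    )


def _build_registry() -> dict:
    reg: dict[tuple, GeneratorPreset] = {}

    # Untreated controls drift only slightly over 24-72 h in culture:
    # 72 vacuoles / 29% occupancy at 24 h, 81 / 27% at 72 h.
    reg.update([_untreated(0, area=600.0, count=72.0, fraction=0.29)])
    reg.update([_untreated(24, area=610.0, count=76.0, fraction=0.28)])
    reg.update([_untreated(48, area=620.0, count=81.0, fraction=0.27)])

    # Amiodarone (phospholipidosis): unchanged cell area and vacuole-occupied
    # fraction, but 1.8x (5 uM) / 2.6x (10 uM) fewer, hence larger, vacuoles
    # acutely; vacuole counts recover by 48 h wash-out while phospholipid
    # stays elevated (2.9x at 10 uM R48).
    amio = {
        (5.0, 0): dict(cell_area=600.0, count=40.0, fraction=0.29, phos_net=6_000.0),
        (5.0, 24): dict(cell_area=610.0, count=60.0, fraction=0.285, phos_net=6_000.0),
        (5.0, 48): dict(cell_area=620.0, count=78.0, fraction=0.27, phos_net=5_400.0),
        (10.0, 0): dict(cell_area=600.0, count=27.7, fraction=0.29, phos_net=7_500.0),
        (10.0, 24): dict(cell_area=610.0, count=50.0, fraction=0.285, phos_net=8_400.0),
        (10.0, 48): dict(cell_area=620.0, count=79.0, fraction=0.27, phos_net=8_700.0),
    }
    for (conc, rec), kw in amio.items():
        reg[condition_key("amiodarone", conc, rec)] = _make(
            f"amiodarone_{conc:g}uM_R{rec}", **kw
        )

    # Staurosporine (pro-apoptotic): at 1 uM the cell shrinks to 12% of the
    # untreated area with 9 vacuoles occupying 9.8%; irreversible, so all
    # time points share the acute parameters.  Condensed nuclei occupy a
    # larger area fraction of the shrunken cell.
    for rec in (0, 24, 48):
        reg[condition_key("staurosporine", 1.0, rec)] = _make(
            f"staurosporine_1uM_R{rec}",
            cell_area=72.0,
            cell_sd=10.0,
            nucleus_fraction=0.18,
            count=9.0,
            dispersion=10.0,
            fraction=0.098,
            radius_sd=0.08,
        )
        reg[condition_key("staurosporine", 0.1, rec)] = _make(
            f"staurosporine_0.1uM_R{rec}",
            cell_area=520.0,
            count=58.0,
            fraction=0.27,
        )

    # Fluticasone: morphometry indistinguishable from untreated; phospholipid
    # rises only after wash-out at 50 uM (2.6x at R24, 1.8x at R48).
    flu_phos = {(10.0, 0): 3_000.0, (10.0, 24): 3_000.0, (10.0, 48): 3_000.0,
                (50.0, 0): 3_000.0, (50.0, 24): 7_800.0, (50.0, 48): 5_400.0}
    untreated_by_rec = {0: (600.0, 72.0, 0.29), 24: (610.0, 76.0, 0.28), 48: (620.0, 81.0, 0.27)}
    for (conc, rec), net in flu_phos.items():
        area, count, frac = untreated_by_rec[rec]
        reg[condition_key("fluticasone", conc, rec)] = _make(
            f"fluticasone_{conc:g}uM_R{rec}",
            cell_area=area, count=count, fraction=frac, phos_net=net,
        )

    # Salbutamol: no morphometric or phospholipid response at either dose.
    for conc in (10.0, 50.0):
        for rec in (0, 24, 48):
            area, count, frac = untreated_by_rec[rec]
            reg[condition_key("salbutamol", conc, rec)] = _make(
                f"salbutamol_{conc:g}uM_R{rec}",
                cell_area=area, count=count, fraction=frac,
            )
    return reg


DEFAULT_PRESETS: dict = _build_registry()

_BY_NAME = {p.name: p for p in DEFAULT_PRESETS.values()}
# Convenience aliases used throughout docs and tests.
_BY_NAME["untreated_24h"] = DEFAULT_PRESETS[condition_key("untreated", 0.0, 0)]
_BY_NAME["untreated_72h"] = DEFAULT_PRESETS[condition_key("untreated", 0.0, 48)]
_BY_NAME["staurosporine_1uM_24h"] = DEFAULT_PRESETS[condition_key("staurosporine", 1.0, 0)]
_BY_NAME["amiodarone_5uM_24h"] = DEFAULT_PRESETS[condition_key("amiodarone", 5.0, 0)]
_BY_NAME["amiodarone_10uM_24h"] = DEFAULT_PRESETS[condition_key("amiodarone", 10.0, 0)]


def preset_names() -> list[str]:
    return sorted(_BY_NAME)


def get_preset(name_or_key) -> GeneratorPreset:
    """Look a preset up by alias name or (compound, concentration, recovery) key."""
    if isinstance(name_or_key, GeneratorPreset):
        return name_or_key
    if isinstance(name_or_key, tuple):
        key = condition_key(*name_or_key)
        if key in DEFAULT_PRESETS:
            return DEFAULT_PRESETS[key]
        raise KeyError(f"no preset for condition {name_or_key}")
    if name_or_key in _BY_NAME:
        return _BY_NAME[name_or_key]
    raise KeyError(f"unknown preset {name_or_key!r}; known: {', '.join(preset_names())}")
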