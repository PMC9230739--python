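"""Synthetic ATR-IR study generator for low-dose CPM tablets and granules.

No instrument data ship with this package, so this module generates spectrum
sets with the statistical structure the calibration analysis assumes:

* Seven formulation strengths (4–30 mg chlorpheniramine maleate per 132 mg
  unit) whose excipient loads (lactose monohydrate, tapioca starch,
  croscarmellose sodium, corn starch, magnesium stearate) come from the
  built-in formulation table; mass fractions mix a per-component mid-IR band
  library (Lorentzian by default).
* CPM bands at ~1700 (C=O), ~2900 (C–H stretch), ~1640 (C=N), ~1600 (C=C),
  ~1100 (C–O stretch) and ~880 cm⁻¹ (C–H bend).  Excipient carbohydrates
  carry broad O–H (~3300), C–H (~2920) and strong C–O–C (~1000–1150 cm⁻¹)
  bands that deliberately overlap the analyte's C–O region — the low-dose
  interference problem the calibration must solve.
* Measurement artefacts: multiplicative scatter, linear baseline drift and
  additive noise, all seeded.
* The tablet/granule contrast is encoded solely as ``surface_sd``: ATR reads
  the unit surface, and un-ground compressed tablets present a surface CPM
  fraction that wanders multiplicatively around the mass ratio (so absolute
  spectral error grows with strength — heteroscedastic residuals), while
  ground granule powder presents the true ratio (``surface_sd = 0``).
* Reference values emulate an HPLC assay: truth × mean recovery × seeded
  Gaussian relative noise (defaults: recovery 1.015, RSD 1.26%).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DesignError, ParameterError
from .spectra_core import SpectrumSet, WavenumberGrid

__all__ = [
    "BandSpec",
    "FormulationRow",
    "SyntheticDesign",
    "DEFAULT_BAND_LIBRARY",
    "builtin_formulations",
    "component_signatures",
    "generate_set",
    "simulate_reference",
    "simulate_study",
]

EXCIPIENTS = (
    "lactose_monohydrate",
    "tapioca_starch",
    "croscarmellose_sodium",
    "corn_starch",
    "magnesium_stearate",
)
COMPONENTS = ("cpm",) + EXCIPIENTS


@dataclass(frozen=True)
class BandSpec:
    """One absorption band: center (cm⁻¹), half-width at half-maximum (cm⁻¹),
    peak amplitude (a.u. per unit mass fraction), and line shape."""

    center: float
    width: float
    amplitude: float
    shape: str = "lorentzian"  # | "gaussian"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ParameterError("band width must be > 0")
        if self.amplitude < 0:
            raise ParameterError("band amplitude must be >= 0")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ParameterError(f"unknown band shape {self.shape!r}")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        d = wavenumbers - self.center
        if self.shape == "lorentzian":
            return self.amplitude * self.width ** 2 / (d ** 2 + self.width ** 2)
        return self.amplitude * np.exp(-np.log(2.0) * (d / self.width) ** 2)


@dataclass(frozen=True)
class FormulationRow:
    """One unit formulation: analyte strength plus excipient masses, mg/unit."""

    strength: float  # mg CPM per unit
    excipients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strength <= 0:
            raise ParameterError("strength must be positive")
        missing = set(EXCIPIENTS) - set(self.excipients)
        if missing:
            raise ParameterError(f"missing excipient masses: {sorted(missing)}")
        if any(m < 0 for m in self.excipients.values()):
            raise ParameterError("excipient masses must be >= 0")

    @property
    def total_mass(self) -> float:
        return self.strength + sum(self.excipients.values())

    def mass_fractions(self) -> np.ndarray:
        """Fractions in COMPONENTS order (analyte first)."""
        total = self.total_mass
        return np.array([self.strength / total]
                        + [self.excipients[e] / total for e in EXCIPIENTS])


def builtin_formulations() -> list[FormulationRow]:
    """The seven study formulations (constant 132.0 mg unit mass).

    Lactose is the filler traded against the analyte load; the other
    excipients are fixed across strengths.
    """
    lactose = {4.0: 80.0, 8.0: 76.0, 10.0: 74.0, 15.0: 69.0,
               20.0: 64.0, 25.0: 59.0, 30.0: 54.0}
    rows = []
    for strength, lac in lactose.items():
        rows.append(FormulationRow(
            strength=strength,
            excipients={
                "lactose_monohydrate": lac,
                "tapioca_starch": 40.0,
                "croscarmellose_sodium": 3.7,
                "corn_starch": 3.6,
                "magnesium_stearate": 0.7,
            },
        ))
    return rows


# Band library: analyte bands from its functional groups; excipient bands are
# generic carbohydrate / stearate features chosen to overlap the analyte's
# C-O region (the realistic interference for a low-dose formulation).
DEFAULT_BAND_LIBRARY: dict[str, tuple[BandSpec, ...]] = {
    "cpm": (
        BandSpec(1700.0, 12.0, 0.90),   # C=O (maleate carbonyl)
        BandSpec(2900.0, 30.0, 0.50),   # C-H stretch
        BandSpec(1640.0, 10.0, 0.70),   # C=N
        BandSpec(1600.0, 10.0, 0.60),   # aromatic C=C
        BandSpec(1100.0, 15.0, 0.80),   # C-O stretch
        BandSpec(880.0, 12.0, 0.40),    # aromatic C-H bend
    ),
    "lactose_monohydrate": (
        BandSpec(3350.0, 120.0, 0.55),  # broad O-H
        BandSpec(2920.0, 25.0, 0.25),
        BandSpec(1070.0, 40.0, 0.90),   # C-O-C, overlaps analyte C-O
        BandSpec(1030.0, 25.0, 0.60),
        BandSpec(900.0, 15.0, 0.20),
    ),
    "tapioca_starch": (
        BandSpec(3300.0, 130.0, 0.50),
        BandSpec(2925.0, 25.0, 0.22),
        BandSpec(1150.0, 20.0, 0.40),
        BandSpec(1015.0, 35.0, 0.85),
    ),
    "croscarmellose_sodium": (
        BandSpec(3330.0, 120.0, 0.45),
        BandSpec(2900.0, 25.0, 0.20),
        BandSpec(1590.0, 30.0, 0.50),   # carboxylate, overlaps analyte C=C
        BandSpec(1050.0, 35.0, 0.70),
    ),
    "corn_starch": (
        BandSpec(3320.0, 125.0, 0.50),
        BandSpec(2928.0, 25.0, 0.22),
        BandSpec(1155.0, 20.0, 0.35),
        BandSpec(1020.0, 35.0, 0.80),
    ),
    "magnesium_stearate": (
        BandSpec(2916.0, 12.0, 1.20),   # CH2 asymmetric stretch
        BandSpec(2849.0, 10.0, 0.90),   # CH2 symmetric stretch
        BandSpec(1576.0, 15.0, 0.50),   # carboxylate
        BandSpec(1466.0, 12.0, 0.30),
    ),
}


def _default_grid() -> WavenumberGrid:
    # 400-4000 cm-1 at 2 cm-1 spacing: a typical DTGS ATR acquisition grid
    return WavenumberGrid(np.arange(400.0, 4000.0 + 1.0, 2.0))


@dataclass(frozen=True)
class SyntheticDesign:
    """Full specification of one simulated measurement campaign."""

    form: str  # "tablet" | "granule"
    strengths: tuple[float, ...] = (4.0, 8.0, 10.0, 15.0, 20.0, 25.0, 30.0)
    replicates_per_strength: int = 30
    grid: WavenumberGrid = field(default_factory=_default_grid)
    band_library: dict[str, tuple[BandSpec, ...]] = field(
        default_factory=lambda: dict(DEFAULT_BAND_LIBRARY))
    noise_sd: float = 0.002          # a.u., additive per grid point
    scatter_sd: float = 0.05         # multiplicative, mean 1
    baseline_offset_sd: float = 0.01  # a.u.
    baseline_slope_sd: float = 2e-5   # a.u. per cm-1
    surface_sd: float = 0.08          # relative jitter of the surface CPM fraction
    reference_recovery: float = 1.015  # mean HPLC recovery (101.5%)
    reference_rsd: float = 0.0126      # HPLC repeatability, relative sd
    seed: int = 0

    def __post_init__(self) -> None:
        if self.form not in ("tablet", "granule"):
            raise DesignError(f"form must be tablet or granule, got {self.form!r}")
        if not self.strengths or any(s <= 0 for s in self.strengths):
            raise DesignError("strengths must be positive")
        if self.replicates_per_strength < 1:
            raise DesignError("need at least one replicate per strength")
        for name, value in (("noise_sd", self.noise_sd),
                            ("scatter_sd", self.scatter_sd),
                            ("baseline_offset_sd", self.baseline_offset_sd),
                            ("baseline_slope_sd", self.baseline_slope_sd),
                            ("surface_sd", self.surface_sd),
                            ("reference_rsd", self.reference_rsd)):
            if value < 0:
                raise DesignError(f"{name} must be >= 0")
        if self.reference_recovery <= 0:
            raise DesignError("reference_recovery must be > 0")
        missing = set(COMPONENTS) - set(self.band_library)
        if missing:
            raise DesignError(f"band library missing components: {sorted(missing)}")

    @classmethod
    def tablet(cls, seed: int = 0, **overrides) -> "SyntheticDesign":
        """The 210-unit tablet campaign: 7 strengths x 30 replicates."""
        return cls(form="tablet", replicates_per_strength=30, seed=seed,
                   **overrides)

    @classmethod
    def granule(cls, seed: int = 0, **overrides) -> "SyntheticDesign":
        """The 70-sample granule campaign: 7 strengths x 10 replicates,
        no surface-composition jitter (powder is ground before measurement)."""
        overrides.setdefault("surface_sd", 0.0)
        return cls(form="granule", replicates_per_strength=10, seed=seed,
                   **overrides)

    def noiseless(self) -> "SyntheticDesign":
        """Copy with every stochastic term switched off."""
        return replace(self, noise_sd=0.0, scatter_sd=0.0,
                       baseline_offset_sd=0.0, baseline_slope_sd=0.0,
                       surface_sd=0.0, reference_rsd=0.0,
                       reference_recovery=1.0)


def component_signatures(grid: WavenumberGrid,
                         band_library: dict[str, tuple[BandSpec, ...]]
                         ) -> np.ndarray:
    """Pure-component spectra, shape (len(COMPONENTS), len(grid))."""
    w = grid.values
    return np.array([
        np.sum([band.profile(w) for band in band_library[c]], axis=0)
        for c in COMPONENTS
    ])


def generate_set(design: SyntheticDesign) -> SpectrumSet:
    """Generate one seeded spectrum set with true contents attached.

    Each sample's absorbance is the mass-fraction mixture of the component
    signatures, times (1 + scatter), plus a linear baseline and additive
    noise.  ``reference`` holds the TRUE content (the nominal strength —
    whole-unit content is exact in this simulator; the measured-surface CPM
    fraction is what ``surface_sd`` perturbs).  Use
    :func:`simulate_reference` for HPLC-like assay values.
    """
    rng = np.random.default_rng(design.seed)
    formulations = {f.strength: f for f in builtin_formulations()}
    for s in design.strengths:
        if s not in formulations:
            raise DesignError(
                f"no builtin formulation for strength {s} mg "
                f"(available: {sorted(formulations)})"
            )
    signatures = component_signatures(design.grid, design.band_library)
    w = design.grid.values
    w_centered = w - w.mean()

    n = len(design.strengths) * design.replicates_per_strength
    matrix = np.empty((n, len(design.grid)))
    ids: list[str] = []
    nominal = np.empty(n)

    row = 0
    for strength in design.strengths:
        fractions = formulations[strength].mass_fractions()
        for rep in range(design.replicates_per_strength):
            frac = fractions.copy()
            if design.surface_sd > 0:
                # surface enrichment/depletion of the analyte, balanced by
                # the filler so the fractions still sum to one
                delta = design.surface_sd * frac[0] * rng.standard_normal()
                delta = np.clip(delta, -frac[0], frac[1])
                frac[0] += delta
                frac[1] -= delta
            clean = frac @ signatures
            scatter = 1.0 + design.scatter_sd * rng.standard_normal()
            offset = design.baseline_offset_sd * rng.standard_normal()
            slope = design.baseline_slope_sd * rng.standard_normal()
            noise = design.noise_sd * rng.standard_normal(len(design.grid))
            matrix[row] = clean * scatter + offset + slope * w_centered + noise
            ids.append(f"{design.form}_{strength:g}mg_{rep + 1:02d}")
            nominal[row] = strength
            row += 1

    metadata = pd.DataFrame({
        "sample_id": ids,
        "form": design.form,
        "nominal_mg": nominal,
        "true_mg": nominal,
    })
    return SpectrumSet(grid=design.grid, matrix=matrix, sample_ids=ids,
                       reference=nominal.copy(), metadata=metadata)


def simulate_reference(true_contents, recovery: float = 1.015,
                       rsd: float = 0.0126,
                       seed: int | np.random.Generator | None = 0) -> np.ndarray:
    """HPLC-like reference values: ``true × recovery × (1 + ε)``,
    ε ~ N(0, rsd²) from a seeded generator."""
    true_contents = np.asarray(true_contents, dtype=float)
    if recovery <= 0:
        raise ParameterError("recovery must be > 0")
    if rsd < 0:
        raise ParameterError("rsd must be >= 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    eps = rng.standard_normal(true_contents.shape)
    return true_contents * recovery * (1.0 + rsd * eps)


def simulate_study(design: SyntheticDesign,
                   reference_seed: int | None = None) -> SpectrumSet:
    """Generate spectra and replace truth with simulated HPLC reference values.

    The true contents stay available as ``metadata['true_mg']``.  The
    reference seed defaults to ``design.seed + 1`` so spectra and assay noise
    are independent streams of one campaign seed.
    """
    sset = generate_set(design)
    if reference_seed is None:
        reference_seed = design.seed + 1
    ref = simulate_reference(sset.reference, design.reference_recovery,
                             design.reference_rsd, reference_seed)
    return sset.with_reference(ref)
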