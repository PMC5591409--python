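"""Synthetic serum 1H-NMR cohort generator.

Produces frequency-domain spectra for three clinical classes — healthy
controls (C), drug-responder (R) and drug-resistant / non-responder (NR)
epilepsy patients — with known ground-truth metabolite concentrations, so the
whole binning → OPLS-DA → validation → quantification pipeline can be
exercised and checked for parameter recovery without any acquired data.

Model
-----
Each metabolite is a set of first-order multiplets (binomial line intensity
ratios, line spacing J) with Lorentzian lineshape; the integrated area of a
metabolite's signal is proportional to concentration x proton count, with the
same proportionality constant for every species including the TSP internal
standard (1 intensity-area unit per proton-mM). Per-sample concentrations are
drawn from per-class normal distributions truncated at zero; per-sample,
per-metabolite chemical-shift jitter emulates pH/ionic-strength shifts
surviving TSP referencing (TSP itself, being the reference, is never
jittered). A polynomial baseline, a broad residual-water Lorentzian inside the
water exclusion window, and white noise complete the trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import Spectrum

__all__ = [
    "MultipletDef",
    "QuantWindow",
    "MetaboliteSpec",
    "MetaboliteLibrary",
    "AcquisitionParams",
    "CohortDesign",
    "GROUPS",
    "tsp_final_concentration",
    "build_default_library",
    "load_library",
    "sample_concentrations",
    "render_spectrum",
    "simulate_cohort",
]

GROUPS = ("C", "R", "NR")

#: packaged default library of serum metabolite signatures + class distributions
_DEFAULT_LIBRARY_PATH = Path(__file__).parent / "data" / "serum_library.yaml"


def tsp_final_concentration(
    stock_mM: float = 5.07, added_ul: float = 70.0, total_ul: float = 700.0
) -> float:
    """Final concentration of the TSP internal standard after reconstitution:
    a 70 µl aliquot of 5.07 mM stock in a 700 µl NMR sample gives 0.507 mM."""
    if total_ul <= 0 or added_ul < 0 or stock_mM < 0:
        raise ValueError("volumes must be positive and concentration non-negative")
    return stock_mM * added_ul / total_ul


@dataclass(frozen=True)
class MultipletDef:
    """A first-order multiplet: `multiplicity` lines spaced J Hz apart with
    binomial (Pascal-triangle) intensity ratios summing to 1."""

    center_ppm: float
    multiplicity: int
    J_hz: float
    protons: int
    linewidth_hz: float

    def __post_init__(self) -> None:
        if self.protons < 1:
            raise ValueError("protons must be >= 1")
        if self.linewidth_hz <= 0:
            raise ValueError("linewidth must be > 0")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")
        if self.J_hz < 0:
            raise ValueError("J must be >= 0")

    def line_offsets_ppm(self, frequency_mhz: float) -> np.ndarray:
        """Line positions relative to the multiplet center, in ppm."""
        m = self.multiplicity
        j_ppm = self.J_hz / frequency_mhz
        return (np.arange(m) - (m - 1) / 2.0) * j_ppm

    def line_weights(self) -> np.ndarray:
        """Binomial intensity ratios (1 — 1:1 — 1:2:1 — ...), summing to 1."""
        m = self.multiplicity
        w = np.array([math.comb(m - 1, i) for i in range(m)], dtype=float)
        return w / w.sum()

    def gamma_ppm(self, frequency_mhz: float) -> float:
        """Half-width at half-maximum in ppm."""
        return self.linewidth_hz / frequency_mhz


@dataclass(frozen=True)
class QuantWindow:
    """Designated integration window for targeted quantification."""

    window_ppm: tuple[float, float]
    multiplets: tuple[int, ...]
    overlap: bool = False


@dataclass(frozen=True)
class MetaboliteSpec:
    name: str
    multiplets: tuple[MultipletDef, ...]
    distributions: dict[str, tuple[float, float]] = field(default_factory=dict)
    sources: dict[str, str] = field(default_factory=dict)
    quantification: QuantWindow | None = None

    def __post_init__(self) -> None:
        if sum(m.protons for m in self.multiplets) <= 0:
            raise ValueError(f"{self.name}: total proton count must be > 0")
        for grp, (mean, sd) in self.distributions.items():
            if mean < 0 or sd < 0:
                raise ValueError(f"{self.name}/{grp}: mean and SD must be >= 0")

    @property
    def total_protons(self) -> int:
        return sum(m.protons for m in self.multiplets)


@dataclass(frozen=True)
class MetaboliteLibrary:
    metabolites: tuple[MetaboliteSpec, ...]
    reference: MetaboliteSpec
    reference_concentration_mM: float

    def __post_init__(self) -> None:
        names = [m.name for m in self.metabolites]
        if len(set(names)) != len(names):
            raise ValueError("metabolite names must be unique")
        if self.reference_concentration_mM <= 0:
            raise ValueError("reference concentration must be > 0")

    def __getitem__(self, name: str) -> MetaboliteSpec:
        for m in self.metabolites:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.metabolites]


def _parse_multiplet(d: dict) -> MultipletDef:
    return MultipletDef(
        center_ppm=float(d["center_ppm"]),
        multiplicity=int(d["multiplicity"]),
        J_hz=float(d["J_hz"]),
        protons=int(d["protons"]),
        linewidth_hz=float(d["linewidth_hz"]),
    )


def _parse_spec(d: dict) -> MetaboliteSpec:
    quant = None
    if "quantification" in d:
        q = d["quantification"]
        quant = QuantWindow(
            window_ppm=(float(q["window_ppm"][0]), float(q["window_ppm"][1])),
            multiplets=tuple(int(i) for i in q["multiplets"]),
            overlap=bool(q.get("overlap", False)),
        )
    dists, sources = {}, {}
    for grp, dd in d.get("distributions", {}).items():
        dists[str(grp)] = (float(dd["mean_mM"]), float(dd["sd_mM"]))
        sources[str(grp)] = str(dd.get("source", "default"))
    return MetaboliteSpec(
        name=str(d["name"]),
        multiplets=tuple(_parse_multiplet(m) for m in d["multiplets"]),
        distributions=dists,
        sources=sources,
        quantification=quant,
    )


def load_library(path: str | Path) -> MetaboliteLibrary:
    """Load a metabolite library from its YAML file (schema documented in the
    packaged ``data/serum_library.yaml``)."""
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh)
    ref = _parse_spec(raw["reference"])
    lib = MetaboliteLibrary(
        metabolites=tuple(_parse_spec(m) for m in raw["metabolites"]),
        reference=ref,
        reference_concentration_mM=float(raw["reference"]["concentration_mM"]),
    )
    for m in lib.metabolites + (lib.reference,):
        for mult in m.multiplets:
            if not -0.1 <= mult.center_ppm <= 8.6:
                raise ValueError(
                    f"{m.name}: multiplet at {mult.center_ppm} ppm outside [-0.1, 8.6]"
                )
    return lib


def build_default_library() -> MetaboliteLibrary:
    """The packaged serum library: the eight metabolites with published
    per-class concentration distributions, four additional metabolites with
    flagged default distributions (including the overlapping 0.92-ppm
    2-OH-butyrate / 2-OH-valerate triplet pair), and the TSP reference
    singlet (0.0 ppm, 9 protons, 0.507 mM)."""
    return load_library(_DEFAULT_LIBRARY_PATH)


@dataclass(frozen=True)
class AcquisitionParams:
    """Spectrometer/output-grid parameters for frequency-domain synthesis.

    noise_sd and water_amplitude are expressed as fractions of the TSP peak
    height so they stay meaningful if the reference concentration changes.
    """

    frequency_mhz: float = 499.0
    ppm_min: float = -0.5
    ppm_max: float = 9.5
    n_points: int = 16384
    noise_sd: float = 0.002
    baseline_coeffs: tuple[float, ...] = ()
    jitter_sd_ppm: float = 0.003
    water_center_ppm: float = 4.79
    water_amplitude: float = 0.2
    water_linewidth_hz: float = 15.0

    def __post_init__(self) -> None:
        if self.frequency_mhz <= 0:
            raise ValueError("frequency must be > 0")
        if self.n_points < 2 or self.ppm_min >= self.ppm_max:
            raise ValueError("invalid output grid")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")

    def grid(self) -> np.ndarray:
        return np.linspace(self.ppm_min, self.ppm_max, self.n_points)


@dataclass(frozen=True)
class CohortDesign:
    n_controls: int
    n_responders: int
    n_nonresponders: int
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_controls, self.n_responders, self.n_nonresponders) < 0:
            raise ValueError("group sizes must be >= 0")
        if self.n_controls + self.n_responders + self.n_nonresponders == 0:
            raise ValueError("all group sizes are zero")

    @property
    def sizes(self) -> dict[str, int]:
        return {"C": self.n_controls, "R": self.n_responders,
                "NR": self.n_nonresponders}


def sample_concentrations(
    library: MetaboliteLibrary, group: str, rng: np.random.Generator
) -> dict[str, float]:
    """Draw one concentration per metabolite from the group's normal
    distribution truncated at zero (resampling until non-negative)."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    out: dict[str, float] = {}
    for m in library.metabolites:
        if group not in m.distributions:
            raise ValueError(f"{m.name}: no distribution for group {group!r}")
        mean, sd = m.distributions[group]
        if sd == 0:
            out[m.name] = mean
            continue
        c = rng.normal(mean, sd)
        while c < 0:
            c = rng.normal(mean, sd)
        out[m.name] = c
    return out


def _lorentzian(x: np.ndarray, x0: float, gamma: float) -> np.ndarray:
    """Unit-area Lorentzian lineshape."""
    return (gamma / np.pi) / ((x - x0) ** 2 + gamma**2)


def tsp_peak_height(library: MetaboliteLibrary, acq: AcquisitionParams) -> float:
    """Analytic peak height of the TSP singlet (area units per ppm)."""
    ref = library.reference
    area = library.reference_concentration_mM * ref.total_protons
    gamma = ref.multiplets[0].gamma_ppm(acq.frequency_mhz)
    return area / (np.pi * gamma)


def _add_metabolite(
    trace: np.ndarray,
    grid: np.ndarray,
    spec: MetaboliteSpec,
    conc_mM: float,
    acq: AcquisitionParams,
    shift: float,
) -> None:
    for mult in spec.multiplets:
        gamma = mult.gamma_ppm(acq.frequency_mhz)
        offsets = mult.line_offsets_ppm(acq.frequency_mhz)
        weights = mult.line_weights()
        area = conc_mM * mult.protons
        for off, w in zip(offsets, weights):
            trace += area * w * _lorentzian(grid, mult.center_ppm + shift + off, gamma)


def render_spectrum(
    assignment: dict[str, float],
    library: MetaboliteLibrary,
    acq: AcquisitionParams | None = None,
    rng: np.random.Generator | None = None,
    sample_id: str = "",
    group: str | None = None,
) -> Spectrum:
    """Render one frequency-domain spectrum from a concentration assignment.

    Intensity = baseline + residual-water hump + noise + the Lorentzian
    multiplet lines of every metabolite plus the TSP reference; each species'
    total integrated area equals concentration x protons (one area unit per
    proton-mM for all species).
    """
    acq = acq or AcquisitionParams()
    rng = rng or np.random.default_rng(0)
    if acq.ppm_min > -0.1 or acq.ppm_max < 8.6:
        raise ValueError("output grid must cover [-0.1, 8.6] ppm")
    missing = [m.name for m in library.metabolites if m.name not in assignment]
    if missing:
        raise ValueError(f"assignment missing metabolites: {missing}")

    grid = acq.grid()
    trace = np.zeros_like(grid)

    # jitter drawn for every metabolite (deterministic draw count), reference fixed
    jitters = {
        m.name: (rng.normal(0.0, acq.jitter_sd_ppm) if acq.jitter_sd_ppm > 0 else 0.0)
        for m in library.metabolites
    }
    for m in library.metabolites:
        _add_metabolite(trace, grid, m, assignment[m.name], acq, jitters[m.name])
    _add_metabolite(
        trace, grid, library.reference, library.reference_concentration_mM, acq, 0.0
    )

    tsp_h = tsp_peak_height(library, acq)
    if acq.water_amplitude > 0:
        gamma_w = acq.water_linewidth_hz / acq.frequency_mhz
        height = acq.water_amplitude * tsp_h
        trace += height * np.pi * gamma_w * _lorentzian(grid, acq.water_center_ppm, gamma_w)
    if acq.baseline_coeffs:
        trace += np.polyval(acq.baseline_coeffs[::-1], grid)
    if acq.noise_sd > 0:
        trace += rng.normal(0.0, acq.noise_sd * tsp_h, size=grid.size)

    return Spectrum(grid, trace, sample_id=sample_id, group=group)


def simulate_cohort(
    design: CohortDesign,
    library: MetaboliteLibrary | None = None,
    acq: AcquisitionParams | None = None,
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Simulate a full cohort.

    Returns the spectra (one per subject, unique ids, groups C/R/NR) and the
    ground-truth table with one row per sample x metabolite
    (``sample_id  group  metabolite  conc_mM``). Fully reproducible from
    ``design.seed``.
    """
    library = library or build_default_library()
    acq = acq or AcquisitionParams()
    rng = np.random.default_rng(design.seed)
    spectra: list[Spectrum] = []
    truth_rows: list[tuple[str, str, str, float]] = []
    for group in GROUPS:
        for i in range(design.sizes[group]):
            sid = f"{group}{i + 1:02d}"
            assignment = sample_concentrations(library, group, rng)
            spectra.append(
                render_spectrum(assignment, library, acq, rng, sample_id=sid, group=group)
            )
            for name in library.names:
                truth_rows.append((sid, group, name, assignment[name]))
    truth = pd.DataFrame(
        truth_rows, columns=["sample_id", "group", "metabolite", "conc_mM"]
    )
    return spectra, truth
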