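"""Shared fixtures: the packaged library, the standard bucket grid, and a
small simulated cohort reused across test modules."""

import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from nmrmetab import (
    AcquisitionParams,
    CohortDesign,
    assemble_bin_matrix,
    bin_spectrum,
    build_bin_grid,
    build_default_library,
    normalize_percent,
    simulate_cohort,
)
from nmrmetab.simulate import MetaboliteLibrary, MetaboliteSpec, MultipletDef, QuantWindow

STANDARD_EXCLUSIONS = [(4.64, 5.2), (5.28, 6.6)]


@pytest.fixture(scope="session")
def library():
    return build_default_library()


@pytest.fixture(scope="session")
def standard_grid():
    return build_bin_grid(0.6, 8.6, 0.04, STANDARD_EXCLUSIONS)


@pytest.fixture(scope="session")
def small_cohort(library):
    """A (12 C, 0 R, 10 NR) cohort: fast but separable, used by multivariate
    and validation tests."""
    design = CohortDesign(12, 0, 10, seed=11)
    return simulate_cohort(design, library, AcquisitionParams())


@pytest.fixture(scope="session")
def small_matrix(small_cohort, standard_grid):
    spectra, _ = small_cohort
    binned = [normalize_percent(bin_spectrum(s, standard_grid)) for s in spectra]
    return assemble_bin_matrix(binned, standard_grid)


def make_library(specs, ref_conc=0.507):
    """Build a minimal library: each entry is (name, center, multiplicity, J,
    protons, dists) with dists a {group: (mean, sd)} map; the reference is the
    usual 9-proton singlet at 0 ppm."""
    mets = []
    for name, center, mult, j, protons, dists in specs:
        mets.append(
            MetaboliteSpec(
                name=name,
                multiplets=(MultipletDef(center, mult, j, protons, 1.0),),
                distributions=dict(dists),
                sources={g: "default" for g in dists},
                quantification=QuantWindow((center - 0.05, center + 0.05), (0,)),
            )
        )
    ref = MetaboliteSpec(
        name="TSP",
        multiplets=(MultipletDef(0.0, 1, 0.0, 9, 1.0),),
        quantification=QuantWindow((-0.05, 0.05), (0,)),
    )
    return MetaboliteLibrary(
        metabolites=tuple(mets), reference=ref, reference_concentration_mM=ref_conc
    )
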