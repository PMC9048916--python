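import numpy as np
import pandas as pd
import pytest

from plastotrans.normalize import normalize_scans
from plastotrans.plastome import (
    OrfModel,
    PlastomeAnnotation,
    StudyDesign,
    assign_probes,
    default_annotation,
    default_probe_layout,
)
from plastotrans.simulate import NoiseModel, cold_shift_preset, simulate_study


@pytest.fixture(scope="session")
def annotation():
    return default_annotation()


@pytest.fixture(scope="session")
def probes(annotation):
    return assign_probes(default_probe_layout(annotation), annotation)


@pytest.fixture(scope="session")
def design():
    return StudyDesign()


@pytest.fixture(scope="session")
def toy_annotation():
    """Three genes on a 3 kb axis: single-exon, two-exon, and minus-strand."""
    return PlastomeAnnotation(
        [
            OrfModel("geneA", "+", [(100, 400, 1)], True, "PSII"),
            OrfModel("geneB", "+", [(600, 700, 1), (900, 1100, 2)], False, "NDH"),
            OrfModel("geneC", "-", [(1900, 2200, 1), (1500, 1800, 2)], True, "other"),
        ],
        genome_length=3000,
    )


@pytest.fixture(scope="session")
def preset_study(design, annotation, probes):
    """One simulated cold-shift study with the shipped effect preset."""
    effects = cold_shift_preset(probes)
    scans, truth = simulate_study(design, annotation, probes, effects, NoiseModel(), seed=11)
    return scans, truth


@pytest.fixture(scope="session")
def normalized(preset_study, probes):
    scans, truth = preset_study
    abundances, exon_abundances, table, manifest = normalize_scans(scans, probes)
    return {
        "abundances": abundances,
        "exon_abundances": exon_abundances,
        "table": table,
        "manifest": manifest,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def null_study(design, annotation, probes):
    """A zero-effect study (pure noise) for null-behaviour checks."""
    scans, truth = simulate_study(design, annotation, probes, [], NoiseModel(), seed=23)
    return scans, truth
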