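import numpy as np
import pandas as pd
import pytest

from neutrokit import ExpressionMatrix, SimulationDesign
from neutrokit.simulate import simulate_expression, simulate_model
from neutrokit.specificity import load_neutrophil_marker_panel, panel_to_summary


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples, two populations with 2 replicates each."""
    values = pd.DataFrame(
        {
            "a1": [100.0, 10.0, 500.0],
            "a2": [140.0, 12.0, 520.0],
            "b1": [30.0, 200.0, 480.0],
            "b2": [34.0, 210.0, 470.0],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
    populations = pd.DataFrame(
        {
            "population_id": ["A", "A", "B", "B"],
            "group_class": ["neutrophil", "neutrophil",
                            "non_neutrophil", "non_neutrophil"],
            "condition": ["BL", "BL", "", ""],
        },
        index=pd.Index(["a1", "a2", "b1", "b2"], name="sample_id"),
    )
    return ExpressionMatrix(values, populations)


@pytest.fixture(scope="session")
def marker_summary() -> pd.DataFrame:
    """Published 31-gene neutrophil marker panel as a specificity summary."""
    return panel_to_summary(load_neutrophil_marker_panel())


@pytest.fixture(scope="session")
def synthetic_default():
    """Default desk-scale synthetic dataset (noise CV 0.1) with its model."""
    design = SimulationDesign(seed=11)
    matrix, truth = simulate_expression(design)
    model, planted = simulate_model(design, truth)
    return design, matrix, truth, model, planted


@pytest.fixture(scope="session")
def synthetic_clean():
    """Zero-noise synthetic dataset: replicates equal population means."""
    design = SimulationDesign(seed=7, noise_cv=0.0)
    matrix, truth = simulate_expression(design)
    return design, matrix, truth
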