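import numpy as np
import pytest

from clockworks import synthetic as syn


@pytest.fixture(scope="session")
def small_cell_matrix():
    """Two-type cell x gene matrix with planted markers and a co-expression pair."""
    spec = syn.CellSimSpec(
        cell_types=[
            syn.CellTypeSpec("astrocyte", 0.5, ["Gfap", "Aqp4", "Sox9"]),
            syn.CellTypeSpec("scn_neuron", 0.5, ["Slc32a1", "Avp"]),
        ],
        n_cells=800,
        n_genes=60,
        baseline_mean=2.0,
        marker_fold=8.0,
        coexpr_pair=syn.CoexprPairSpec(
            "Anxa2",
            "S100a10",
            {
                "astrocyte": (0.3, 0.1, 0.1, 0.5),
                "scn_neuron": (0.7, 0.1, 0.15, 0.05),
            },
        ),
        seed=3,
    )
    return syn.simulate_cells(spec)


@pytest.fixture(scope="session")
def clean_cosine_trace():
    """Noiseless 24 h cosine peaking at t = 6 h, PMT-like sampling."""
    return syn.simulate_trace(
        syn.TraceSimSpec(
            duration_h=120, dt_h=0.1, period_h=24.0, phase_h=6.0, amplitude=1.0,
            noise_sd=0.0, seed=0,
        )
    )


def cosine_values_by_timepoint(peak_ct, amplitude, noise_sd, n_reps, rng,
                               timepoints=(0.0, 6.0, 12.0, 18.0, 24.0)):
    """Replicated cosine observations keyed by CT, shared across rhythm tests."""
    return {
        ct: amplitude * np.cos(2 * np.pi * ((ct % 24.0) - peak_ct) / 24.0)
        + rng.normal(0.0, noise_sd, n_reps)
        for ct in timepoints
    }
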