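import pandas as pd
import pytest

from crosskill import KillingMatrix


@pytest.fixture
def two_line_matrix():
    """Tiny hand-built killing matrix: 2 lines (one per species), 6 compounds."""
    values = pd.DataFrame(
        [[90.0, 80.0, 70.0, 40.0, 55.0, 10.0],
         [85.0, 75.0, 60.0, 30.0, 45.0, 5.0]],
        index=["D418", "17-3X"],
        columns=[f"C{i}" for i in range(6)])
    species = pd.Series({"D418": "dog", "17-3X": "human"})
    return KillingMatrix(values, species)


@pytest.fixture
def four_line_matrix():
    """Two identical 'human' and two identical 'dog' profiles."""
    values = pd.DataFrame(
        [[10.0, 20.0, 30.0], [10.0, 20.0, 30.0],
         [60.0, 70.0, 80.0], [60.0, 70.0, 80.0]],
        index=["H1", "H2", "D1", "D2"],
        columns=["C0", "C1", "C2"])
    species = pd.Series({"H1": "human", "H2": "human", "D1": "dog", "D2": "dog"})
    return KillingMatrix(values, species)


@pytest.fixture
def toy_wells():
    """One plate, 2 compounds x 2 replicates + 3 controls, hand-computable."""
    rows = [
        ("P1", "A01", "treated", "L1", "human", "CA", 1, 5000.0),
        ("P1", "A02", "treated", "L1", "human", "CA", 2, 5000.0),
        ("P1", "A03", "treated", "L1", "human", "CB", 1, 2000.0),
        ("P1", "A04", "treated", "L1", "human", "CB", 2, 4000.0),
        ("P1", "B01", "vehicle_control", "L1", "human", "", 0, 9000.0),
        ("P1", "B02", "vehicle_control", "L1", "human", "", 0, 10000.0),
        ("P1", "B03", "vehicle_control", "L1", "human", "", 0, 11000.0),
    ]
    return pd.DataFrame(rows, columns=["plate_id", "well", "role", "cell_line",
                                       "species", "compound_id", "replicate",
                                       "luminescence_rlu"])
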