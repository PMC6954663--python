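import numpy as np
import pytest

from foldevents import ReactivityMatrix, ThresholdSet


def random_matrix(rng, n_lengths=None, n_positions=None, start_length=None,
                  na_fraction=0.0, scale=1.0):
    """A random valid reactivity matrix for property tests."""
    n_lengths = n_lengths or rng.integers(5, 21)
    n_positions = n_positions or rng.integers(3, 21)
    start_length = start_length or int(rng.integers(1, 30))
    lengths = np.arange(start_length, start_length + n_lengths)
    positions = np.arange(1, n_positions + 1)
    values = rng.gamma(1.0, scale, size=(n_lengths, n_positions))
    if na_fraction > 0:
        mask = rng.random(values.shape) < na_fraction
        values[mask] = np.nan
    return ReactivityMatrix(lengths, positions, values, replicate_id="rand")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def default_ts():
    return ThresholdSet(p_up=0.3, p_down=0.3, i_up=0.6, i_down=0.6,
                        r_up=0.5, r_down=0.5, m_floor=0.2)


def step_matrix(low=0.2, high=1.5, step_at=50, lengths=None, n_positions=1):
    """Single-column (by default) step from ``low`` to ``high`` at ``step_at``."""
    if lengths is None:
        lengths = np.arange(30, 81)
    lengths = np.asarray(lengths)
    col = np.where(lengths >= step_at, high, low).astype(float)
    values = np.tile(col[:, None], (1, n_positions))
    return ReactivityMatrix(lengths, np.arange(1, n_positions + 1), values)


def column_series(m, position=1):
    """Column of ``m`` as a list with None for undefined cells."""
    col = m.column(position)
    return [None if np.isnan(v) else float(v) for v in col]
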