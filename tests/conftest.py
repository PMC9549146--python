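import numpy as np
import pytest

from ieegcontrast.geometry import Contact, ContactTable
from ieegcontrast.spectral import GammaPowerTraces, gpt_time_axis


@pytest.fixture(scope="session")
def times():
    return gpt_time_axis()


@pytest.fixture
def contact():
    return Contact(id="e1c1", subject="S1", xyz=(10.0, 20.0, 30.0),
                   label="fusiform", hemisphere="LH")


@pytest.fixture
def make_gpts(times):
    """Factory for synthetic per-contact gamma power traces.

    ``make_gpts(seed, n_per_class, effect, window)`` returns traces whose
    angry trials get ``effect`` added inside ``window`` (seconds).
    """
    def _make(seed=0, n_per_class=60, effect=0.0, window=(0.2, 0.6),
              label="fusiform", hemisphere="LH", subject="S1", contact_id="e1c1",
              xyz=(10.0, 20.0, 30.0)):
        rng = np.random.default_rng(seed)
        c = Contact(id=contact_id, subject=subject, xyz=xyz,
                    label=label, hemisphere=hemisphere)
        conditions = np.array(["angry"] * n_per_class + ["happy"] * n_per_class)
        values = rng.normal(size=(2 * n_per_class, len(times)))
        if effect:
            mask = (times >= window[0]) & (times <= window[1])
            values[np.ix_(conditions == "angry", mask)] += effect
        return GammaPowerTraces(values=values, times=times, contact=c, conditions=conditions)
    return _make


@pytest.fixture
def grid_table():
    """Nine contacts of one subject on a 10 mm grid plus one far-away subject."""
    contacts = [
        Contact(id=f"g{i}", subject="S1", xyz=(10.0 * (i % 3), 10.0 * (i // 3), 0.0),
                label="fusiform", hemisphere="LH")
        for i in range(9)
    ]
    contacts.append(Contact(id="far", subject="S2", xyz=(0.0, 0.0, 0.0),
                            label="insula", hemisphere="RH"))
    return ContactTable(contacts)
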