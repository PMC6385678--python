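import numpy as np
import pytest

from wepath.kinetics import BindingStateDefs
from wepath.toy_binding_sim import ToyParams
from wepath.we_engine import IterationRecord


@pytest.fixture(scope="session")
def toy_params() -> ToyParams:
    return ToyParams()


@pytest.fixture(scope="session")
def binding_defs() -> BindingStateDefs:
    return BindingStateDefs()


def make_linear_records(
    labels: list[str],
    weight: float = 1.0,
    defs: BindingStateDefs | None = None,
) -> list[IterationRecord]:
    """Scripted single-walker run: one iteration per entry of ``labels``.

    The walker follows the given instantaneous state sequence (the first
    entry is the pre-run state, not an iteration); arrivals and history
    labels are derived exactly as the engine would derive them.
    """
    records = []
    prev_state = labels[0]
    hist = "U"
    for t, lab in enumerate(labels[1:], start=1):
        arrivals = []
        if lab not in ("none", prev_state):
            arrivals.append((0, lab, weight, prev_state, hist))
        if lab == "unbound":
            hist = "U"
        elif lab == "bound":
            hist = "B"
        records.append(
            IterationRecord(
                iteration=t,
                weights=np.array([weight]),
                pcoords=np.zeros((1, 2)),
                bins=np.zeros(1, dtype=int),
                parent_idx=np.array([0 if t > 1 else -1]),
                state_labels=np.array([lab], dtype=object),
                history=np.array([hist], dtype=object),
                roots=np.zeros(1, dtype=int),
                recycled_flags=np.zeros(1, dtype=bool),
                arrivals=arrivals,
                recycled_weight=0.0,
                post_weights=np.array([weight]),
                post_parent_idx=np.array([0]),
                dyn=None,
            )
        )
        prev_state = lab
    return records
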