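import numpy as np
import pytest

from delaykit import (
    DelaySpec,
    Reaction,
    SpeciesSet,
    build_network,
    make_reaction,
)


@pytest.fixture
def species_x():
    return SpeciesSet(("X",))


@pytest.fixture
def birth_death(species_x):
    """Linear birth-death process: 0 -> X at 10, X -> 0 at 1; stationary Poisson(10)."""
    return build_network(species_x, [
        make_reaction(species_x, {}, {"X": 1}, rate=10.0, name="birth"),
        make_reaction(species_x, {"X": 1}, {}, rate=1.0, name="death"),
    ])


def delayed_birth_network(alpha: float, tau: float):
    """Birth process where every molecule lives exactly tau (M/D/inf queue).

    Each birth adds one X immediately and schedules its removal at t+tau;
    the stationary count is Poisson(alpha * tau).
    """
    sp = SpeciesSet(("X",))
    birth = Reaction(
        reactant_counts=np.zeros(1, dtype=np.int64),
        s_column=np.array([1], dtype=np.int64),
        s_delay_column=np.array([-1], dtype=np.int64),
        rate_constant=alpha,
        delay=DelaySpec.consuming(tau),
        name="birth_with_lifetime",
    )
    return build_network(sp, [birth])


def zero_delay_birth_death():
    """Birth-death where the death channel carries a zero-length delay.

    Distributionally identical to the plain birth-death network; used for
    the zero-delay reduction checks.
    """
    sp = SpeciesSet(("X",))
    return build_network(sp, [
        make_reaction(sp, {}, {"X": 1}, rate=10.0, name="birth"),
        make_reaction(sp, {"X": 1}, {}, rate=1.0,
                      delay=DelaySpec.consuming(0.0), name="death"),
    ])


@pytest.fixture
def mdinf():
    return delayed_birth_network(5.0, 2.0)
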