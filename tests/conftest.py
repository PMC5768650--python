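import numpy as np
import pytest

from bcirace import (Command, CommandEvent, build_regulation_track,
                     default_parameters_2016, track_from_string)

COMMANDS = tuple(Command)


@pytest.fixture(scope="session")
def params():
    return default_parameters_2016()


@pytest.fixture(scope="session")
def regulation_track(params):
    return build_regulation_track(params, seed=1)


def random_case(rng, params, max_fields=4, max_commands=4, codes="NRJS"):
    """One fuzzed (track, command log) pair; log times span the whole race."""
    n_fields = rng.integers(1, max_fields + 1)
    spec = "".join(rng.choice(list(codes)) for _ in range(n_fields))
    track = track_from_string(spec, params)
    # a race never outlasts total_length / punish speed
    t_max = track.total_length / params.s_punish_noinput
    n_cmd = rng.integers(0, max_commands + 1)
    times = np.sort(rng.uniform(0.0, t_max, size=n_cmd))
    log = [CommandEvent(float(t), COMMANDS[rng.integers(3)]) for t in times]
    return track, log
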