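import numpy as np
import pytest

from freeznet.trajectory_io import ArenaCalibration, Trajectory

FRAME_RATE = 30.0


@pytest.fixture
def calib():
    return ArenaCalibration(frame_rate=FRAME_RATE)


def make_trajectory(pos, valid=None, frame_rate=FRAME_RATE, onset=300.0, **kw):
    """Build a Trajectory straight from an (n, 3) position array."""
    pos = np.asarray(pos, dtype=float)
    n = len(pos)
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return Trajectory(
        fish_id=kw.pop("fish_id", "fish"),
        treatment=kw.pop("treatment", ""),
        t=np.arange(n) / frame_rate,
        pos=pos,
        valid=np.asarray(valid, dtype=bool),
        frame_rate=frame_rate,
        protocol_onset=onset,
        **kw,
    )


def write_csv(path, rows, header="frame,x,y,z"):
    path.write_text(header + "\n" + "\n".join(rows) + ("\n" if rows else ""))
    return path
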