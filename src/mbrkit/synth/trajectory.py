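"""Two-state helix-coil trajectory generator with membrane placement.

Emulates a membrane-binding segment switching between conformational
states of differing helical content: a hidden two-state Markov chain
(helix <-> coil) drives, per frame, which backbone conformation is posed
on the membrane and at what target depth and tilt.  The hidden state and
the noisy target pose are recorded as ground truth so downstream
estimators have exact recovery references.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ..errors import InputError
from ..structure import Trajectory
from .helix import HelixSpec, build_ideal_helix
from .membrane import MembraneModelSpec, make_membrane, place_on_membrane

#: degrees of tilt jitter applied per Angstrom of positional noise
TILT_NOISE_PER_A = 2.0


@dataclass
class TwoStateModel:
    """Markov switching model between a helical and a frayed/coil state.

    ``k_hc``/``k_ch`` are per-frame helix->coil and coil->helix switching
    probabilities; each state has a target insertion depth (A) and tilt
    (deg); ``noise_sd`` (A) jitters the depth (and, scaled, the tilt) per
    frame.  Identical ``seed`` yields an identical trajectory.
    """

    k_hc: float = 0.05
    k_ch: float = 0.05
    depth_helix: float = -5.0
    depth_coil: float = 2.0
    tilt_helix: float = 10.0
    tilt_coil: float = 30.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k_hc", "k_ch"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise InputError(f"{name} must be a probability in [0, 1]")

    def stationary_helix_occupancy(self) -> float:
        """Stationary probability of the helix state."""
        if self.k_hc + self.k_ch == 0:
            return 1.0
        return self.k_ch / (self.k_hc + self.k_ch)


def simulate_trajectory(
    model: TwoStateModel,
    helix: HelixSpec,
    membrane: MembraneModelSpec,
    n_frames: int,
    dt_ps: float = 5.0,
    helix_range: tuple[int, int] | None = None,
    start_state: str = "helix",
) -> Trajectory:
    """Simulate an ordered, time-stamped two-state trajectory.

    Frame times are ``i * dt_ps``.  The coil-state conformation applies the
    spec's ``coil_ranges`` (or fully extended dihedrals if none are given);
    the helix state ignores them.  Ground-truth labels recorded per frame:
    ``state`` (1 = helix), ``depth_true`` (A) and ``tilt_true`` (deg).
    """
    if n_frames < 1:
        raise InputError("n_frames must be >= 1")
    rng = np.random.default_rng(model.seed)

    helix_frame = build_ideal_helix(replace(helix, coil_ranges=[]))
    coil_spec = helix if helix.coil_ranges else replace(
        helix, phi=180.0, psi=180.0)
    coil_frame = build_ideal_helix(coil_spec)
    membrane_frame = make_membrane(membrane, seed=int(rng.integers(2**31)))

    if helix_range is None:
        helix_range = (helix.start_resid, helix.start_resid + len(helix.sequence) - 1)

    states = np.empty(n_frames, dtype=int)
    state = 1 if start_state == "helix" else 0
    switch = rng.random(n_frames)
    depth_noise = rng.normal(0.0, model.noise_sd, n_frames)
    tilt_noise = rng.normal(0.0, model.noise_sd * TILT_NOISE_PER_A, n_frames)

    frames = []
    depths = np.empty(n_frames)
    tilts = np.empty(n_frames)
    for i in range(n_frames):
        if state == 1 and switch[i] < model.k_hc:
            state = 0
        elif state == 0 and switch[i] < model.k_ch:
            state = 1
        states[i] = state
        base = helix_frame if state == 1 else coil_frame
        depth = (model.depth_helix if state == 1 else model.depth_coil) + depth_noise[i]
        tilt = float(np.clip(
            (model.tilt_helix if state == 1 else model.tilt_coil) + tilt_noise[i],
            0.0, 90.0))
        posed = place_on_membrane(base, tilt, depth, membrane_frame, helix_range)
        posed.time_ps = i * dt_ps
        frames.append(posed)
        depths[i] = depth
        tilts[i] = tilt

    return Trajectory(frames, labels={
        "state": states,
        "depth_true": depths,
        "tilt_true": tilts,
    })
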