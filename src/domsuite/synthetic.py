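"""Synthetic data with known ground truth for every pipeline stage.

Two generators:

* :func:`generate_matches` draws dyadic win/loss/tie streams from a
  latent linear hierarchy. Each cage has distinct latent dominance values
  d_i; animal i beats j with Bradley–Terry probability
  ``1/(1 + exp(−β (d_i − d_j)))``, ties occur with a fixed probability,
  and any assay can be inverted (the win probability flips), emulating a
  strain in which one assay ranks animals opposite to the others.

* :func:`generate_pose` simulates a two-mouse reward-competition arena:
  a Markov dwell model switches between scripted behavioral states
  (both at the port; one at the port with the other nearby facing away;
  one at the port with the other at the back wall; roaming), rigid
  6-node skeletons are placed per state, Gaussian pixel noise is added,
  and a random fraction of node-frames is masked missing. Per-frame true
  state labels are recorded so clustering recovery is measurable. A
  dwell multiplier can inflate the near-avert state for rank-difference-3
  dyads, planting a known enrichment signal.

Skeletons are rigid templates (nose 25 px ahead of the thorax, forehead
15 px ahead, ears ±8 px lateral of the forehead, tail base 30 px behind)
rotated to a heading; the downstream features depend only on
nose/thorax/port geometry, so no further biomechanical realism is needed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from domsuite.errors import ValidationError
from domsuite.pose_features import PoseRecording
from domsuite.records_io import Assay, MatchRecord, Outcome

DEFAULT_TRIALS_PER_DYAD = {
    Assay.AGONISTIC: 10,
    Assay.URINE: 2,
    Assay.TUBE: 10,
    Assay.REWARD: 6,
}


@dataclass
class HierarchyConfig:
    """Latent-hierarchy match generator settings.

    ``latent`` gives each cage member's dominance value (defaults to four
    equally spaced values); ``beta`` is the Bradley–Terry steepness — at
    the default 2.0 adjacent-ranked animals win ~88% of decisive contests,
    a steep but not deterministic hierarchy. ``trials_per_dyad`` mirrors
    the assays' sampling depth (repeated daily tube matches, one or two
    urine trials, six reward-competition matches).
    """

    n_animals: int = 4
    latent: tuple[float, ...] = (1.5, 0.5, -0.5, -1.5)
    beta: float = 2.0
    tie_prob: float = 0.1
    trials_per_dyad: dict[Assay, int] = field(
        default_factory=lambda: dict(DEFAULT_TRIALS_PER_DYAD)
    )
    inverted_assays: frozenset[Assay] = frozenset()
    n_cages: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.latent) != self.n_animals:
            raise ValidationError("latent scores must match n_animals")
        if len(set(self.latent)) != self.n_animals:
            raise ValidationError("latent scores must be distinct")
        if not 0 <= self.tie_prob < 1:
            raise ValidationError("tie_prob must be in [0, 1)")
        if self.beta < 0:
            raise ValidationError("beta must be non-negative")


def _animal_id(cage: int, idx: int) -> str:
    return f"c{cage}m{idx}"


def generate_matches(
    cfg: HierarchyConfig,
) -> tuple[list[MatchRecord], dict[str, float]]:
    """Draw match records for every assay/cage/dyad/trial.

    Returns the chronologically ordered records and the ground-truth
    latent score per animal id. Fixed seed → identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[MatchRecord] = []
    truth: dict[str, float] = {}
    for cage in range(cfg.n_cages):
        cage_id = f"cage{cage}"
        ids = [_animal_id(cage, i) for i in range(cfg.n_animals)]
        for aid, d in zip(ids, cfg.latent):
            truth[aid] = d
        for assay, n_trials in cfg.trials_per_dyad.items():
            sign = -1.0 if assay in cfg.inverted_assays else 1.0
            order = 0
            for _ in range(n_trials):
                # one round of all dyads per "day", interleaved like the assays
                for i in range(cfg.n_animals):
                    for j in range(i + 1, cfg.n_animals):
                        if rng.random() < cfg.tie_prob:
                            outcome = Outcome.TIE
                        else:
                            p_i = 1.0 / (
                                1.0
                                + np.exp(-cfg.beta * sign * (cfg.latent[i] - cfg.latent[j]))
                            )
                            outcome = (
                                Outcome.A_WINS if rng.random() < p_i else Outcome.B_WINS
                            )
                        records.append(
                            MatchRecord(
                                assay=assay,
                                cage=cage_id,
                                order=order,
                                id_a=ids[i],
                                id_b=ids[j],
                                outcome=outcome,
                            )
                        )
                        order += 1
    return records, truth


class SimState(str, enum.Enum):
    """Scripted arena states the pose generator cycles through."""

    BOTH_AT_PORT = "both_at_port"
    PORT_AND_NEAR_AVERT = "port_and_near_avert"
    PORT_AND_BACKWALL = "port_and_backwall"
    ROAMING = "roaming"


@dataclass
class PoseSimConfig:
    """Arena/pose simulation settings.

    The arena is 640×480 px with the reward port centered on the left
    wall (mirroring an operant box filmed at 30 fps). ``dwell_frames``
    are mean state durations; ``rank_diff3_avert_multiplier`` (> 1)
    inflates the near-avert dwell when ``rank_diff == 3``, planting the
    enrichment signal probed downstream. ``noise_sd`` is per-node
    Gaussian pixel noise; ``missing_fraction`` masks node-frames
    completely at random.
    """

    arena: tuple[float, float] = (640.0, 480.0)
    port: tuple[float, float] = (0.0, 240.0)
    states: tuple[SimState, ...] = (
        SimState.BOTH_AT_PORT,
        SimState.PORT_AND_NEAR_AVERT,
        SimState.PORT_AND_BACKWALL,
        SimState.ROAMING,
    )
    dwell_frames: dict[SimState, float] = field(
        default_factory=lambda: {
            SimState.BOTH_AT_PORT: 300.0,
            SimState.PORT_AND_NEAR_AVERT: 300.0,
            SimState.PORT_AND_BACKWALL: 300.0,
            SimState.ROAMING: 450.0,
        }
    )
    rank_diff3_avert_multiplier: float = 1.0
    rank_diff: int = 1
    noise_sd: float = 2.0
    missing_fraction: float = 0.05
    fps: float = 30.0
    frames: int = 1800
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_fraction < 1:
            raise ValidationError("missing_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.frames < 2:
            raise ValidationError("need at least 2 frames")


def _skeleton(thorax: np.ndarray, heading: float) -> np.ndarray:
    """Rigid 6-node template at ``thorax`` rotated to ``heading`` (radians).

    Node order matches pose_features.NODE_NAMES.
    """
    u = np.array([np.cos(heading), np.sin(heading)])
    perp = np.array([-u[1], u[0]])
    forehead = thorax + 15.0 * u
    return np.stack(
        [
            thorax + 25.0 * u,  # nose
            forehead,
            forehead + 8.0 * perp,  # left ear
            forehead - 8.0 * perp,  # right ear
            thorax,
            thorax - 30.0 * u,  # tail base
        ]
    )


def _heading_to(src: np.ndarray, dst: np.ndarray) -> float:
    d = dst - src
    return float(np.arctan2(d[1], d[0]))


def _state_sequence(cfg: PoseSimConfig, rng: np.random.Generator) -> list[SimState]:
    dwell = dict(cfg.dwell_frames)
    if cfg.rank_diff == 3 and cfg.rank_diff3_avert_multiplier != 1.0:
        dwell[SimState.PORT_AND_NEAR_AVERT] = (
            dwell[SimState.PORT_AND_NEAR_AVERT] * cfg.rank_diff3_avert_multiplier
        )
    seq: list[SimState] = []
    state = cfg.states[rng.integers(len(cfg.states))]
    while len(seq) < cfg.frames:
        run = max(1, int(rng.geometric(1.0 / max(dwell[state], 1.0))))
        seq.extend([state] * run)
        nxt = [s for s in cfg.states if s is not state]
        if nxt:
            state = nxt[rng.integers(len(nxt))]
    return seq[: cfg.frames]


def generate_pose(cfg: PoseSimConfig) -> PoseRecording:
    """Simulate one recording; ``state_truth`` carries the script."""
    rng = np.random.default_rng(cfg.seed)
    port = np.asarray(cfg.port, dtype=float)
    w, h = cfg.arena
    center = np.array([w / 2.0, h / 2.0])
    back_wall_x = w  # far wall, opposite the port
    seq = _state_sequence(cfg, rng)

    coords = np.zeros((2, 6, cfg.frames, 2))
    # roaming random-walk state persists across frames
    roam_pos = rng.uniform([60, 60], [w - 60, h - 60], size=(2, 2))
    roam_heading = rng.uniform(0, 2 * np.pi, size=2)
    port_inward = _heading_to(center, port)  # pointing at the port from inside

    for f, state in enumerate(seq):
        jitter = lambda s=1.5: rng.normal(0.0, s, size=2)  # noqa: E731
        if state is SimState.BOTH_AT_PORT:
            # noses within 15 px of the port, lateral offset keeps bodies apart
            lateral = np.array([0.0, 14.0])
            for a, side in enumerate((+1, -1)):
                nose = port + side * lateral * 0.5 + jitter(3.0)
                nose = port + (nose - port) * min(1.0, 14.0 / max(np.linalg.norm(nose - port), 1e-9))
                thorax = nose - 25.0 * np.array([np.cos(port_inward), np.sin(port_inward)])
                heading = _heading_to(thorax, port)
                coords[a, :, f] = _skeleton(thorax, heading)
        elif state is SimState.PORT_AND_NEAR_AVERT:
            nose = port + jitter(3.0)
            nose = port + (nose - port) * min(1.0, 10.0 / max(np.linalg.norm(nose - port), 1e-9))
            thorax0 = nose - 25.0 * np.array([np.cos(port_inward), np.sin(port_inward)])
            coords[0, :, f] = _skeleton(thorax0, _heading_to(thorax0, port))
            # loser paces ~150 px off the port, facing away from it
            u = np.array([np.cos(port_inward), np.sin(port_inward)])
            perp = np.array([-u[1], u[0]])
            pace = 35.0 * np.sin(2.0 * np.pi * f / 60.0)
            thorax1 = port - 150.0 * u + pace * perp + jitter(4.0)
            away = _heading_to(port, thorax1) + rng.normal(0.0, 0.15)
            coords[1, :, f] = _skeleton(thorax1, away)
        elif state is SimState.PORT_AND_BACKWALL:
            nose = port + jitter(3.0)
            nose = port + (nose - port) * min(1.0, 10.0 / max(np.linalg.norm(nose - port), 1e-9))
            thorax0 = nose - 25.0 * np.array([np.cos(port_inward), np.sin(port_inward)])
            coords[0, :, f] = _skeleton(thorax0, _heading_to(thorax0, port))
            # other animal pressed to the far wall, heading folded away from the port
            thorax1 = np.array([back_wall_x - 15.0, h / 2.0]) + jitter(5.0)
            away = _heading_to(port, thorax1) + rng.normal(0.0, 0.2)
            coords[1, :, f] = _skeleton(thorax1, away)
        else:  # ROAMING: correlated random walk, high velocity
            for a in range(2):
                roam_heading[a] += rng.normal(0.0, 0.4)
                step = 8.0 * np.array(
                    [np.cos(roam_heading[a]), np.sin(roam_heading[a])]
                )
                roam_pos[a] = np.clip(roam_pos[a] + step, [40, 40], [w - 40, h - 40])
                coords[a, :, f] = _skeleton(roam_pos[a], roam_heading[a])

    if cfg.noise_sd > 0:
        coords += rng.normal(0.0, cfg.noise_sd, size=coords.shape)
    if cfg.missing_fraction > 0:
        mask = rng.random((2, 6, cfg.frames)) < cfg.missing_fraction
        # never blank an entire node track
        for a in range(2):
            for nd in range(6):
                if mask[a, nd].sum() > cfg.frames - 2:
                    mask[a, nd, :2] = False
        coords[mask] = np.nan

    return PoseRecording(
        coords=coords,
        port=tuple(port),
        fps=cfg.fps,
        recording_id=f"sim{cfg.seed}",
        state_truth=np.array([s.value for s in seq]),
    )
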