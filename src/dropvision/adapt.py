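"""Sarsa-based adaptation of the image contrast parameter to illumination.

Ambient illumination drifts while the carrier's ink thickness stays
fixed, so the contrast of the captured droplet image varies.  A tabular
on-policy temporal-difference agent (Sarsa) learns, per illumination
bin, a contrast-adjustment parameter ``c`` in [0, 1] that minimises the
mismatch between the resulting segmentation and a reference.

State is the pair (illumination bin, current position on the discrete
``c`` grid); actions nudge ``c`` one grid step down, hold it, or nudge
it up.  An episode ends when the reward reaches ``reward_goal`` (the
segmentation is as good as the reference) or a step cap is hit.  The
reward is the ratio of the reference ("standard") average mismatch
spacing to the real-time one, clipped to [0, 1], so the optimum scores 1
and the learned Q values climb towards 1.

The agent is deliberately tabular: the state space is small (by default
100 illumination bins x 101 contrast levels x 3 actions) and training
happens off-line, so function approximation would add opacity for no
benefit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Protocol, Tuple

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "ACTION_DECREASE",
    "ACTION_HOLD",
    "ACTION_INCREASE",
    "N_ACTIONS",
    "SarsaConfig",
    "ContrastState",
    "QTable",
    "ContrastGrid",
    "IlluminationBins",
    "sarsa_update",
    "epsilon_greedy",
    "apply_contrast",
    "mismatch_spacing",
    "reward",
    "LandscapeEnv",
    "SegmentationContrastEnv",
    "ContrastPolicy",
    "train_contrast_policy",
]

ACTION_DECREASE = 0
ACTION_HOLD = 1
ACTION_INCREASE = 2
N_ACTIONS = 3

_ACTION_DELTA = {ACTION_DECREASE: -1, ACTION_HOLD: 0, ACTION_INCREASE: +1}


@dataclass
class SarsaConfig:
    """Hyper-parameters of the tabular Sarsa learner.

    ``alpha`` (learning rate) and ``gamma`` (discount) default to 0.1 and
    0.9, balancing convergence speed against stability.  Exploration is
    epsilon-greedy with an exponential decay from ``epsilon_start`` to
    ``epsilon_end`` over the episode budget (e-folding length
    ``epsilon_decay`` episodes; defaults to a fifth of the budget).
    """

    alpha: float = 0.1
    gamma: float = 0.9
    epsilon_start: float = 0.9
    epsilon_end: float = 0.05
    epsilon_decay: float | None = None
    episodes: int = 500
    max_steps: int = 120
    reward_goal: float = 0.99
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError(f"gamma must be in (0, 1], got {self.gamma}")
        for name in ("epsilon_start", "epsilon_end"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.episodes < 1:
            raise ValueError("episodes must be >= 1")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")

    def epsilon_at(self, episode: int) -> float:
        """Exploration rate for a (0-based) episode index."""
        decay = self.epsilon_decay or max(self.episodes / 5.0, 1.0)
        return self.epsilon_end + (self.epsilon_start - self.epsilon_end) * math.exp(
            -episode / decay
        )


@dataclass(frozen=True)
class ContrastState:
    """Discrete agent state: illumination bin and contrast-grid index."""

    illum_bin: int
    c_index: int


class QTable:
    """Action-value table, zero-initialised, keyed by (state, action)."""

    def __init__(self) -> None:
        self._values: Dict[Tuple[ContrastState, int], float] = {}

    def get(self, state: ContrastState, action: int) -> float:
        return self._values.get((state, action), 0.0)

    def set(self, state: ContrastState, action: int, value: float) -> None:
        if not math.isfinite(value):
            raise ValueError(f"Q value must be finite, got {value}")
        self._values[(state, action)] = value

    def greedy_action(self, state: ContrastState, n_actions: int = N_ACTIONS) -> int:
        """Argmax over actions; ties break to the lowest action index."""
        best, best_v = 0, self.get(state, 0)
        for a in range(1, n_actions):
            v = self.get(state, a)
            if v > best_v:
                best, best_v = a, v
        return best

    def __len__(self) -> int:
        return len(self._values)


@dataclass
class ContrastGrid:
    """Discrete grid of contrast-adjustment parameters in [0, 1]."""

    c_values: np.ndarray = field(
        default_factory=lambda: np.round(np.linspace(0.0, 1.0, 101), 2)
    )

    def __post_init__(self) -> None:
        self.c_values = np.asarray(self.c_values, dtype=float)
        if self.c_values.ndim != 1 or len(self.c_values) < 2:
            raise ValueError("c_values must be a 1-D grid with >= 2 entries")
        if np.any(np.diff(self.c_values) <= 0):
            raise ValueError("c_values must be strictly increasing")
        if self.c_values[0] < 0.0 or self.c_values[-1] > 1.0:
            raise ValueError("c_values must lie within [0, 1]")

    def __len__(self) -> int:
        return len(self.c_values)


@dataclass
class IlluminationBins:
    """Uniform discretisation of the operating illumination range (Lx)."""

    min_lx: float = 3500.0
    max_lx: float = 3600.0
    n_bins: int = 100

    def __post_init__(self) -> None:
        if not self.max_lx > self.min_lx:
            raise ValueError("max_lx must exceed min_lx")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.min_lx, self.max_lx, self.n_bins + 1)

    def index(self, lx: float) -> int:
        i = int(np.searchsorted(self.edges, lx, side="right") - 1)
        return min(max(i, 0), self.n_bins - 1)


def sarsa_update(
    q: QTable,
    s: ContrastState,
    a: int,
    r: float,
    s_next: ContrastState | None,
    a_next: int | None,
    cfg: SarsaConfig,
) -> QTable:
    """One on-policy temporal-difference backup.

    Q(s,a) += alpha * (r + gamma * Q(s', a') - Q(s,a)), where a' is the
    action actually taken next (not the greedy one -- that would be
    Q-learning).  ``s_next=None`` marks a terminal transition, whose
    bootstrap term is zero.  Mutates and returns ``q``.
    """
    if not math.isfinite(r):
        raise ValueError(f"reward must be finite, got {r}")
    bootstrap = 0.0 if s_next is None or a_next is None else q.get(s_next, a_next)
    td = r + cfg.gamma * bootstrap - q.get(s, a)
    q.set(s, a, q.get(s, a) + cfg.alpha * td)
    return q


def epsilon_greedy(
    q: QTable,
    s: ContrastState,
    epsilon: float,
    rng: np.random.Generator,
    n_actions: int = N_ACTIONS,
) -> int:
    """Explore uniformly with probability epsilon, else exploit greedily."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"epsilon must be in [0, 1], got {epsilon}")
    if n_actions < 1:
        raise ValueError("action set must be non-empty")
    if rng.random() < epsilon:
        return int(rng.integers(n_actions))
    return q.greedy_action(s, n_actions)


def apply_contrast(
    image: np.ndarray, c: float, s_gain: float = 2.0
) -> np.ndarray:
    """Affine contrast stretch about the image mean.

    out = clip(mu + (1 + s_gain * c) * (in - mu), 0, 1); ``c = 0`` is the
    identity and larger ``c`` spreads intensities away from the mean.
    The gain slope ``s_gain`` fixes how the abstract parameter ``c``
    maps to stretch strength.
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"contrast parameter must be in [0, 1], got {c}")
    image = np.asarray(image, dtype=float)
    mu = image.mean()
    return np.clip(mu + (1.0 + s_gain * c) * (image - mu), 0.0, 1.0)


def _boundary_4(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with a 4-neighbour outside the foreground."""
    eroded = ndi.binary_erosion(
        mask, structure=ndi.generate_binary_structure(2, 1), border_value=0
    )
    return mask & ~eroded


def mismatch_spacing(candidate: np.ndarray, reference: np.ndarray) -> float:
    """Average spacing (px) of mismatched pixels from the reference boundary.

    Mismatched pixels are where the candidate and reference masks
    disagree (XOR); each is scored by its Euclidean distance to the
    nearest boundary pixel of the reference foreground, and the mean is
    returned.  Identical masks score 0.
    """
    candidate = np.asarray(candidate, dtype=bool)
    reference = np.asarray(reference, dtype=bool)
    if candidate.shape != reference.shape:
        raise ValueError(
            f"mask shapes differ: {candidate.shape} vs {reference.shape}"
        )
    if not reference.any():
        raise ValueError("reference mask is empty")
    mism = candidate ^ reference
    if not mism.any():
        return 0.0
    boundary = _boundary_4(reference)
    dist = ndi.distance_transform_edt(~boundary)
    return float(dist[mism].mean())


def reward(
    realtime_spacing: float,
    standard_spacing: float,
    eps_num: float = 1e-9,
) -> float:
    """Reward in [0, 1]: standard / real-time mismatch spacing, clipped.

    Matching the reference exactly (or beating it) scores 1; doubling
    the mismatch spacing scores 0.5.  A zero standard with a non-zero
    real-time spacing scores 0.
    """
    if realtime_spacing < 0 or standard_spacing < 0:
        raise ValueError("spacings must be >= 0")
    if standard_spacing == 0.0:
        return 1.0 if realtime_spacing == 0.0 else 0.0
    return min(standard_spacing / max(realtime_spacing, eps_num), 1.0)


class ContrastEnv(Protocol):
    """Environment interface consumed by :func:`train_contrast_policy`."""

    n_bins: int
    grid: ContrastGrid

    def reset(self, illum_bin: int, rng: np.random.Generator) -> ContrastState:
        ...

    def step(
        self, state: ContrastState, action: int
    ) -> Tuple[ContrastState, float, bool]:
        ...


class LandscapeEnv:
    """Environment driven by a fixed reward landscape over (bin, c).

    ``rewards`` has shape (n_bins, n_c); stepping moves the contrast
    index per the action and pays the landscape value at the new index.
    Episodes terminate when the reward reaches ``goal``.
    """

    def __init__(self, rewards: np.ndarray, grid: ContrastGrid, goal: float = 0.99):
        self.rewards = np.asarray(rewards, dtype=float)
        if self.rewards.ndim != 2 or self.rewards.shape[1] != len(grid):
            raise ValueError("rewards must have shape (n_bins, len(grid))")
        self.grid = grid
        self.goal = goal
        self.n_bins = self.rewards.shape[0]

    def reset(self, illum_bin: int, rng: np.random.Generator) -> ContrastState:
        return ContrastState(illum_bin, int(rng.integers(len(self.grid))))

    def step(
        self, state: ContrastState, action: int
    ) -> Tuple[ContrastState, float, bool]:
        j = int(
            np.clip(state.c_index + _ACTION_DELTA[action], 0, len(self.grid) - 1)
        )
        nxt = ContrastState(state.illum_bin, j)
        r = float(self.rewards[state.illum_bin, j])
        return nxt, r, r >= self.goal


class SegmentationContrastEnv:
    """Reward = segmentation quality of a contrast-adjusted scene.

    For each illumination bin the environment holds a grayscale image
    (droplets dark) and a ground-truth mask.  Stepping adjusts ``c``,
    re-binarises the stretched image with Otsu's threshold and scores
    the mask against the truth via :func:`mismatch_spacing`; the reward
    is the standard-to-real-time spacing ratio.
    """

    def __init__(
        self,
        images: List[np.ndarray],
        truths: List[np.ndarray],
        grid: ContrastGrid,
        standard_spacing: float,
        s_gain: float = 2.0,
        goal: float = 0.99,
    ):
        if len(images) != len(truths) or not images:
            raise ValueError("need one (image, truth) pair per illumination bin")
        self.images = images
        self.truths = [np.asarray(t, dtype=bool) for t in truths]
        self.grid = grid
        self.standard_spacing = standard_spacing
        self.s_gain = s_gain
        self.goal = goal
        self.n_bins = len(images)
        self._cache: Dict[Tuple[int, int], float] = {}

    def _reward_at(self, illum_bin: int, c_index: int) -> float:
        key = (illum_bin, c_index)
        if key not in self._cache:
            from .segment import otsu_binarize  # local import avoids a cycle

            adj = apply_contrast(
                self.images[illum_bin], float(self.grid.c_values[c_index]),
                self.s_gain,
            )
            mask = otsu_binarize(adj)
            rt = mismatch_spacing(mask, self.truths[illum_bin])
            self._cache[key] = reward(rt, self.standard_spacing)
        return self._cache[key]

    def reset(self, illum_bin: int, rng: np.random.Generator) -> ContrastState:
        return ContrastState(illum_bin, int(rng.integers(len(self.grid))))

    def step(
        self, state: ContrastState, action: int
    ) -> Tuple[ContrastState, float, bool]:
        j = int(
            np.clip(state.c_index + _ACTION_DELTA[action], 0, len(self.grid) - 1)
        )
        nxt = ContrastState(state.illum_bin, j)
        r = self._reward_at(state.illum_bin, j)
        return nxt, r, r >= self.goal


@dataclass
class ContrastPolicy:
    """Learned mapping illumination bin -> contrast parameter.

    ``c_for_bin[b]`` is the best contrast value observed for bin ``b``
    (best-so-far extraction: a non-converged Q table still yields the
    best parameter seen during training).  ``trace`` logs, per episode,
    the Q value of a tracked state-action pair and the current best
    ``c`` -- the data behind learning-curve plots.
    """

    c_for_bin: np.ndarray
    grid: ContrastGrid
    bin_edges: np.ndarray | None = None
    trace: dict | None = None

    def c_for(self, illum_bin: int) -> float:
        return float(self.c_for_bin[illum_bin])

    def to_dict(self) -> dict:
        d = {
            "c_for_bin": [float(v) for v in self.c_for_bin],
            "c_values": [float(v) for v in self.grid.c_values],
        }
        if self.bin_edges is not None:
            d["bin_edges"] = [float(v) for v in self.bin_edges]
        return d


def train_contrast_policy(
    env: ContrastEnv,
    cfg: SarsaConfig,
    grid: ContrastGrid | None = None,
    bin_edges: np.ndarray | None = None,
) -> ContrastPolicy:
    """Run epsilon-greedy Sarsa episodes and extract the per-bin policy.

    Illumination bins are visited round-robin.  The returned policy is
    best-so-far: per bin, the contrast value with the highest reward
    observed during training (falling back to the grid midpoint for bins
    that earned no reward).  The trace records, per episode, the Q value
    of a fixed tracked state-action pair and the running best ``c`` of
    the episode's bin.
    """
    grid = grid or env.grid
    rng = np.random.default_rng(cfg.seed)
    q = QTable()
    n_c = len(grid)
    best: Dict[int, Tuple[float, int]] = {}  # bin -> (reward, c_index)
    tracked = (ContrastState(0, n_c // 2), ACTION_HOLD)
    trace: dict = {"episode": [], "q_tracked": [], "c_best": [], "reward": []}

    for ep in range(cfg.episodes):
        eps = cfg.epsilon_at(ep)
        b = ep % env.n_bins
        s = env.reset(b, rng)
        a = epsilon_greedy(q, s, eps, rng)
        last_r = 0.0
        for _ in range(cfg.max_steps):
            s2, r, done = env.step(s, a)
            last_r = r
            cur = best.get(b)
            if cur is None or r > cur[0]:
                best[b] = (r, s2.c_index)
            if done:
                sarsa_update(q, s, a, r, None, None, cfg)
                break
            a2 = epsilon_greedy(q, s2, eps, rng)
            sarsa_update(q, s, a, r, s2, a2, cfg)
            s, a = s2, a2
        trace["episode"].append(ep)
        trace["q_tracked"].append(q.get(*tracked))
        trace["c_best"].append(
            float(grid.c_values[best[b][1]]) if b in best else float("nan")
        )
        trace["reward"].append(last_r)

    c_for_bin = np.full(env.n_bins, float(grid.c_values[n_c // 2]))
    for b, (_, j) in best.items():
        c_for_bin[b] = float(grid.c_values[j])
    if len(best) < env.n_bins:
        warnings.warn(
            f"{env.n_bins - len(best)} illumination bins were never visited; "
            "their policy entries default to the grid midpoint",
            stacklevel=2,
        )
    return ContrastPolicy(
        c_for_bin=c_for_bin, grid=grid, bin_edges=bin_edges, trace=trace
    )
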