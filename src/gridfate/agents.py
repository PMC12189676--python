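"""Value-learning agents over the lattice MDP.

Three interchangeable learners share the environment interface:

* tabular Q-learning with epsilon-greedy exploration (one row per lattice
  node, eight action columns);
* an actor-critic pair of two-layer perceptrons over the latent state
  vectors, with entropy-regularized policy updates;
* a double DQN with online/target networks and an experience replay buffer.

Training dynamics are tracked through slow exponential moving averages
(coefficients 0.005/0.995) of the maximal Q-value (value methods) or the
state value (actor-critic), plus 100-episode sliding-window mean returns
used for the convergence rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._nn import MLP, Adam, sigmoid, smooth_l1, softmax
from .env import ACTIONS, GridEnv, ReplayBuffer, Transition

__all__ = [
    "epsilon_schedule",
    "QTable",
    "q_update",
    "ActorCriticNets",
    "actor_critic_update",
    "DDQNNets",
    "ddqn_targets",
    "ddqn_update",
    "TrainingTrace",
    "track_ema",
    "Policy",
    "train",
]

EMA_COEF = 0.005
WINDOW = 100  # episodes per sliding convergence window


def epsilon_schedule(
    t: float,
    eps_max: float = 0.9,
    eps_min: float = 0.01,
    rate: float = 0.01,
    tau: float = 1000.0,
) -> float:
    """Exploration probability after ``t`` training steps.

    ``eps_min + (eps_max - eps_min) * exp(-rate * t / tau)`` with defaults
    ``eps_max=0.9``, ``eps_min=0.01``, ``rate=0.01``, ``tau=1000``.
    """
    if t < 0:
        raise ValueError("step t must be >= 0")
    return eps_min + (eps_max - eps_min) * np.exp(-rate * t / tau)


@dataclass
class QTable:
    """Zero-initialized |nodes| x 8 action-value table."""

    values: np.ndarray
    alpha: float = 0.1
    gamma: float = 0.97

    @classmethod
    def zeros(cls, n_nodes: int, alpha: float = 0.1, gamma: float = 0.97) -> "QTable":
        return cls(values=np.zeros((n_nodes, len(ACTIONS))), alpha=alpha, gamma=gamma)


def q_update(table: QTable, tr: Transition) -> QTable:
    """One temporal-difference update; terminal transitions bootstrap 0."""
    boot = 0.0 if tr.done else table.gamma * table.values[tr.next_state].max()
    td = tr.reward + boot - table.values[tr.state, tr.action]
    table.values[tr.state, tr.action] += table.alpha * td
    return table


class ActorCriticNets:
    """Policy and value perceptrons sharing the latent input space.

    The policy head squashes its logits through ``1 + 5 * sigmoid`` before
    the softmax, bounding them to [1, 6] so the policy never collapses to a
    deterministic distribution; entropy regularization (``lambda_ent``,
    default 0.01) further promotes exploration.
    """

    def __init__(self, n_in: int, hidden: int = 64, lr: float = 1e-3,
                 gamma: float = 0.97, lambda_ent: float = 0.01, seed: int = 0):
        self.policy = MLP(n_in, len(ACTIONS), hidden=hidden, seed=seed)
        self.value = MLP(n_in, 1, hidden=hidden, seed=seed + 1)
        self.opt_policy = Adam(self.policy, lr=lr)
        self.opt_value = Adam(self.value, lr=lr)
        self.gamma = gamma
        self.lambda_ent = lambda_ent

    def action_probs(self, s: np.ndarray) -> np.ndarray:
        logits = self.policy.forward(s)
        return softmax(1.0 + 5.0 * sigmoid(logits))[0]

    def state_value(self, s: np.ndarray) -> float:
        return float(self.value.forward(s)[0, 0])


def actor_critic_update(nets: ActorCriticNets, tr: Transition,
                        s: np.ndarray, s_next: np.ndarray) -> float:
    """Advantage update from one transition; returns the TD error.

    ``s``/``s_next`` are the latent vectors of ``tr.state``/``tr.next_state``.
    The critic regresses on the TD target; the actor follows the policy
    gradient of ``-log pi(a|s) * delta`` plus the entropy penalty.
    """
    gamma, lam = nets.gamma, nets.lambda_ent
    v_s = nets.state_value(s)
    v_next = 0.0 if tr.done else nets.state_value(s_next)
    delta = tr.reward + gamma * v_next - v_s
    if not np.isfinite(delta):
        raise FloatingPointError(
            f"non-finite TD error (r={tr.reward}, V(s)={v_s}, V(s')={v_next})"
        )

    # critic: d/dV of (V - target)^2
    cache_v = {}
    nets.value.forward(s, cache_v)
    nets.opt_value.step(nets.value.backward(cache_v, np.array([[-2.0 * delta]])))

    # actor: backprop through softmax(1 + 5*sigmoid(logits))
    cache_p = {}
    logits = nets.policy.forward(s, cache_p)
    sig = sigmoid(logits)
    p = softmax(1.0 + 5.0 * sig)
    logp = np.log(p)
    # d(-delta * log p[a])/du + lambda * d(sum p log p)/du, u = squashed logits
    one_hot = np.zeros_like(p)
    one_hot[0, tr.action] = 1.0
    d_u = -delta * (one_hot - p)
    d_u += lam * p * (logp - (p * logp).sum())
    d_logits = d_u * 5.0 * sig * (1.0 - sig)
    nets.opt_policy.step(nets.policy.backward(cache_p, d_logits))
    return float(delta)


class DDQNNets:
    """Online and target Q-networks for double DQN."""

    def __init__(self, n_in: int, hidden: int = 64, lr: float = 1e-3,
                 gamma: float = 0.97, tau: float = 0.005,
                 hard_update_every: int | None = None, seed: int = 0):
        self.online = MLP(n_in, len(ACTIONS), hidden=hidden, seed=seed)
        self.target = self.online.clone()
        self.opt = Adam(self.online, lr=lr)
        self.gamma = gamma
        self.tau = tau
        self.hard_update_every = hard_update_every
        self.updates = 0

    def q_online(self, s: np.ndarray) -> np.ndarray:
        return self.online.forward(s)

    def q_target(self, s: np.ndarray) -> np.ndarray:
        return self.target.forward(s)

    def sync_target(self) -> None:
        if self.hard_update_every is not None:
            if self.updates % self.hard_update_every == 0:
                self.target.copy_from(self.online, tau=1.0)
        else:
            self.target.copy_from(self.online, tau=self.tau)


def ddqn_targets(nets: DDQNNets, batch: list, state_of) -> np.ndarray:
    """Double-Q bootstrap targets ``y = r + gamma * Q_target(s', a*) (1-d)``.

    The bootstrap action ``a*`` is the argmax of the ONLINE network at the
    next state; only its value is read from the target network.
    """
    S_next = np.stack([state_of(tr.next_state) for tr in batch])
    r = np.array([tr.reward for tr in batch])
    d = np.array([float(tr.done) for tr in batch])
    a_star = np.argmax(nets.q_online(S_next), axis=1)  # online selects
    q_next = nets.q_target(S_next)[np.arange(len(batch)), a_star]  # target evaluates
    return r + nets.gamma * q_next * (1.0 - d)


def ddqn_update(nets: DDQNNets, batch: list, state_of) -> float:
    """Double-Q minibatch update; returns the mean smooth-L1 loss.

    ``state_of`` maps a node id to its latent vector.
    """
    S = np.stack([state_of(tr.state) for tr in batch])
    a = np.array([tr.action for tr in batch])
    y = ddqn_targets(nets, batch, state_of)

    cache = {}
    q = nets.online.forward(S, cache)
    q_sa = q[np.arange(len(batch)), a]
    loss, dloss = smooth_l1(q_sa - y)
    d_out = np.zeros_like(q)
    d_out[np.arange(len(batch)), a] = dloss / len(batch)
    nets.opt.step(nets.online.backward(cache, d_out))
    nets.updates += 1
    nets.sync_target()
    return float(loss.mean())


@dataclass
class TrainingTrace:
    """EMA of the learning signal plus per-episode returns."""

    ema: list = field(default_factory=list)
    episode_returns: list = field(default_factory=list)
    converged: bool = False
    _ema_state: float = 0.0

    def window_means(self, window: int = WINDOW) -> np.ndarray:
        """Trailing ``window``-episode mean return at each episode end."""
        r = np.asarray(self.episode_returns, dtype=float)
        if r.size < window:
            return np.array([])
        c = np.concatenate([[0.0], np.cumsum(r)])
        return (c[window:] - c[:-window]) / window


def track_ema(trace: TrainingTrace, observation: float) -> TrainingTrace:
    """Slow EMA: ``x_bar <- 0.005 * x + 0.995 * x_bar`` (initialized at 0)."""
    trace._ema_state = EMA_COEF * observation + (1.0 - EMA_COEF) * trace._ema_state
    trace.ema.append(trace._ema_state)
    return trace


@dataclass
class Policy:
    """A learned policy: per-node action probabilities."""

    kind: str  # "greedy-q" | "actor"
    _probs_fn: object = None

    def action_probs(self, node: int) -> np.ndarray:
        return self._probs_fn(node)

    def sample(self, node: int, rng: np.random.Generator) -> int:
        p = self.action_probs(node)
        return int(rng.choice(len(p), p=p))


def _converged(trace: TrainingTrace, tol: float, patience: int) -> bool:
    means = trace.window_means()
    if means.size < patience + 1:
        return False
    return bool(np.all(np.abs(np.diff(means[-(patience + 1):])) < tol))


def train(
    env: GridEnv,
    agent_kind: str = "q",
    episodes: int = 1000,
    seed: int = 0,
    alpha: float = 0.1,
    gamma: float = 0.97,
    lr: float = 1e-3,
    hidden: int = 64,
    buffer_capacity: int = 10_000,
    batch_size: int = 64,
    tol: float = 1e-3,
    patience: int = 10,
    early_stop: bool = True,
) -> tuple[np.ndarray, TrainingTrace, Policy]:
    """Run episodic training and return (node value map, trace, policy).

    The value map is the critic's view of each mapped node: max-Q for the
    value-based learners, V(s) for actor-critic; NaN on unmapped nodes.
    Convergence is declared when the trailing 100-episode mean return moves
    by less than ``tol`` over ``patience`` consecutive episodes; if the
    episode budget runs out first the result is returned with
    ``trace.converged=False`` and a warning.
    """
    if agent_kind not in ("q", "ac", "ddqn"):
        raise ValueError(f"unknown agent kind {agent_kind!r}")
    rng = np.random.default_rng(seed)
    env.rng = np.random.default_rng(seed + 1)
    trace = TrainingTrace()
    n_nodes = env.grid.n_nodes
    n_actions = len(ACTIONS)

    if agent_kind == "q":
        table = QTable.zeros(n_nodes, alpha=alpha, gamma=gamma)
    else:
        d_in = env.states.shape[1]
        if agent_kind == "ac":
            nets = ActorCriticNets(d_in, hidden=hidden, lr=lr, gamma=gamma,
                                   seed=seed)
        else:
            nets = DDQNNets(d_in, hidden=hidden, lr=lr, gamma=gamma, seed=seed)
            buffer = ReplayBuffer(capacity=buffer_capacity)

    global_step = 0
    for _ in range(episodes):
        node = env.reset()
        ep_return = 0.0
        while True:
            s = env.state_vector(node)
            if agent_kind == "q":
                eps = epsilon_schedule(global_step)
                if rng.random() < eps:
                    a = int(rng.integers(n_actions))
                else:
                    a = int(np.argmax(table.values[node]))
            elif agent_kind == "ac":
                a = int(rng.choice(n_actions, p=nets.action_probs(s)))
            else:
                eps = epsilon_schedule(global_step, rate=0.1)
                if rng.random() < eps:
                    a = int(rng.integers(n_actions))
                else:
                    a = int(np.argmax(nets.q_online(s)[0]))
            tr = env.step(a)
            ep_return += tr.reward
            if agent_kind == "q":
                q_update(table, tr)
                track_ema(trace, float(table.values[tr.state].max()))
            elif agent_kind == "ac":
                actor_critic_update(nets, tr, s, env.state_vector(tr.next_state))
                track_ema(trace, nets.state_value(s))
            else:
                buffer.push(tr)
                if len(buffer) >= buffer.min_fill_fraction * buffer.capacity:
                    ddqn_update(nets, buffer.sample(batch_size, rng),
                                env.state_vector)
                track_ema(trace, float(nets.q_online(s)[0].max()))
            global_step += 1
            node = tr.next_state
            if tr.done:
                break
        trace.episode_returns.append(ep_return)
        if early_stop and _converged(trace, tol, patience):
            trace.converged = True
            break

    if not trace.converged:
        trace.converged = _converged(trace, tol, patience)
    if not trace.converged:
        warnings.warn(
            "episode budget exhausted before the 100-episode return window "
            "stabilized; returning the current learner state",
            stacklevel=2,
        )

    value_map = np.full(n_nodes, np.nan)
    mapped = env.grid.mapped_nodes
    if agent_kind == "q":
        value_map[mapped] = table.values[mapped].max(axis=1)
        policy = Policy("greedy-q", _probs_fn=_greedy_probs(table.values))
    elif agent_kind == "ac":
        S = env.states[mapped]
        value_map[mapped] = nets.value.forward(S)[:, 0]
        probs = softmax(1.0 + 5.0 * sigmoid(nets.policy.forward(S)))
        policy = Policy("actor", _probs_fn=_lookup_probs(mapped, probs))
    else:
        S = env.states[mapped]
        q_all = nets.online.forward(S)
        value_map[mapped] = q_all.max(axis=1)
        policy = Policy("greedy-q", _probs_fn=_lookup_greedy(mapped, q_all))
    return value_map, trace, policy


def _greedy_probs(values: np.ndarray):
    def fn(node: int) -> np.ndarray:
        p = np.zeros(values.shape[1])
        p[np.argmax(values[node])] = 1.0
        return p

    return fn


def _lookup_probs(mapped: np.ndarray, probs: np.ndarray):
    index = {int(n): i for i, n in enumerate(mapped)}

    def fn(node: int) -> np.ndarray:
        return probs[index[int(node)]]

    return fn


def _lookup_greedy(mapped: np.ndarray, q_all: np.ndarray):
    index = {int(n): i for i, n in enumerate(mapped)}

    def fn(node: int) -> np.ndarray:
        p = np.zeros(q_all.shape[1])
        p[np.argmax(q_all[index[int(node)]])] = 1.0
        return p

    return fn
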