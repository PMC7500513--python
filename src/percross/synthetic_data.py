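"""Synthetic dyadic sessions with known ground truth.

Two fidelity levels:

* :func:`generate_events` / :func:`generate_model_data` draw event-level
  data directly from the path model's generative process — click indicators,
  a synchrony-mixture of click times, piecewise-probit individual success,
  joint success, and correlated ordinal PAS responses.  This is the level
  used for parameter-recovery studies.
* :func:`generate_behavioral` runs the torus simulator with stochastic
  search-and-dwell controllers, producing full trajectories whose clicks can
  be pushed through classification, descriptives and the model end to end.

Default parameter values emulate the marginals of the original study (about
80% click rate, about 72% correct clicks, PAS mass shifting upward under
joint success, inter-click delays concentrated below a few seconds in
synchronised trials); they are generator settings with stored ground truth,
not estimates.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy.special import ndtr
from scipy.stats import truncnorm

from .bayes_model import ModelData, ordinal_probit_probs
from .environment import ObjectKind, WorldConfig, simulate_trial, torus_distance
from .trial_data import ClickEvent, PASResponse, SessionDataset, TeamRecord, TrialRecord

__all__ = [
    "SyntheticConfig",
    "generate_events",
    "generate_model_data",
    "generate_behavioral",
    "delay_mixture_cdf",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground truth and design sizes for the generator.

    The delay model for trials where both players click is a mixture: with
    probability ``p_sync`` the two clicks are separated by an
    Exponential(mean ``sync_mean_s``) gap (a synchronised joint decision);
    otherwise both click times are independent Uniform(0, T).
    """

    n_teams: int = 10
    n_trials: int = 20
    trial_duration: float = 60.0
    click_prob: float = 0.80
    pas_missing_prob: float = 0.013
    # delay model
    p_sync: float = 0.15
    sync_mean_s: float = 1.5
    delay_window: float = 3.0
    # individual-success submodel truth
    mu_a: float = 0.30
    sigma_a: float = 0.40
    sigma_b: float = 0.19
    mu_tau_S: float = 3.2
    sigma_tau_S: float = 2.0
    lambda_S: float = 0.70
    # joint-success submodel truth (used when joint success is drawn from
    # its own probit rather than derived from the two individual successes)
    mu_c: float = -0.43
    sigma_c: float = 0.40
    lambda_G: float = 1.01
    # PAS submodel truth
    sigma_u: float = 0.50
    sigma_v: float = 0.30
    mu_tau_P: float = 5.1
    sigma_tau_P: float = 2.5
    gamma_S: float = -0.16
    gamma_G: float = 0.69
    gamma_D: float = 0.14
    kappa: tuple[float, float, float] = (-0.85, 0.55, 1.60)
    rho: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("click_prob", "pas_missing_prob", "p_sync"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        if not (-1.0 < self.rho < 1.0):
            raise ValueError("rho must be in (-1, 1)")
        if not np.all(np.diff(self.kappa) > 0):
            raise ValueError("cutpoints must be strictly increasing")


def delay_mixture_cdf(d: float, cfg: SyntheticConfig) -> float:
    """Closed-form P(inter-click delay < d) under the mixture delay model."""
    T = cfg.trial_duration
    p_unif = 1.0 - ((T - d) / T) ** 2
    trunc_norm = 1.0 - math.exp(-T / cfg.sync_mean_s)
    p_exp = (1.0 - math.exp(-d / cfg.sync_mean_s)) / trunc_norm
    return cfg.p_sync * p_exp + (1.0 - cfg.p_sync) * p_unif


def _draw_truncnorm(rng, mu, sd, lo, hi, size):
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


def _draw_individual_truth(cfg: SyntheticConfig, rng) -> dict:
    I = 2 * cfg.n_teams
    T = cfg.n_trials
    return {
        "a": cfg.mu_a + cfg.sigma_a * rng.standard_normal(I),
        "b": np.abs(cfg.sigma_b * rng.standard_normal(I)),
        "tau_S": _draw_truncnorm(rng, cfg.mu_tau_S, cfg.sigma_tau_S, 1.0, T, I),
        "u": cfg.sigma_u * rng.standard_normal(I),
        "v": np.abs(cfg.sigma_v * rng.standard_normal(I)),
        "tau_P": _draw_truncnorm(rng, cfg.mu_tau_P, cfg.sigma_tau_P, 1.0, T, I),
        "c": cfg.mu_c + cfg.sigma_c * rng.standard_normal(cfg.n_teams),
    }


def _click_times(cfg: SyntheticConfig, rng) -> tuple[float, float]:
    """Click times of a both-click trial under the synchrony mixture."""
    T = cfg.trial_duration
    if rng.uniform() < cfg.p_sync:
        gap = rng.exponential(cfg.sync_mean_s)
        while gap >= T:
            gap = rng.exponential(cfg.sync_mean_s)
        t1 = rng.uniform(0.0, T - gap)
        t2 = t1 + gap
        if rng.uniform() < 0.5:
            t1, t2 = t2, t1
        return t1, t2
    return rng.uniform(0.0, T), rng.uniform(0.0, T)


def _pas_pair(eta1, eta2, rho, kappa, rng):
    """Correlated ordinal draws from the latent bivariate normal."""
    e1 = rng.standard_normal()
    e2 = rho * e1 + math.sqrt(1.0 - rho * rho) * rng.standard_normal()
    kappa = np.asarray(kappa)
    y1 = 1 + int(np.sum(eta1 + e1 > kappa))
    y2 = 1 + int(np.sum(eta2 + e2 > kappa))
    return y1, y2


def _trial_events(cfg, truth, j, t, rng, joint_mode):
    """Simulate one trial; returns per-player click/S/Y plus trial-level G, D."""
    T = cfg.trial_duration
    clicked = rng.uniform(size=2) < cfg.click_prob
    times = [None, None]
    if clicked.all():
        times = list(_click_times(cfg, rng))
        delay = abs(times[0] - times[1])
        D = int(delay < cfg.delay_window)
    else:
        D = 0
        for p in range(2):
            if clicked[p]:
                times[p] = rng.uniform(0.0, T)
    S = [None, None]
    for p in range(2):
        if clicked[p]:
            i = 2 * j + p
            eta = (
                truth["a"][i]
                + truth["b"][i] * (min(t, truth["tau_S"][i]) - 1.0)
                + cfg.lambda_S * D
            )
            S[p] = int(rng.uniform() < ndtr(eta))
    if joint_mode == "probit":
        G = int(rng.uniform() < ndtr(truth["c"][j] + cfg.lambda_G * D))
    else:
        G = int(clicked.all() and S[0] == 1 and S[1] == 1)
    eta_Y = [None, None]
    for p in range(2):
        if clicked[p]:
            i = 2 * j + p
            eta_Y[p] = (
                truth["u"][i]
                + truth["v"][i] * (min(t, truth["tau_P"][i]) - 1.0)
                + cfg.gamma_S * S[p]
                + cfg.gamma_G * G
                + cfg.gamma_D * D
            )
    Y = [None, None]
    if clicked.all():
        Y = list(_pas_pair(eta_Y[0], eta_Y[1], cfg.rho, cfg.kappa, rng))
    else:
        for p in range(2):
            if clicked[p]:
                probs = ordinal_probit_probs(eta_Y[p], np.asarray(cfg.kappa))
                Y[p] = 1 + int(rng.choice(4, p=probs))
    for p in range(2):
        if Y[p] is not None and rng.uniform() < cfg.pas_missing_prob:
            Y[p] = None
    return clicked, times, S, G, D, Y


def generate_model_data(cfg: SyntheticConfig | None = None, seed: int | None = None):
    """Draw observation-level design arrays from the full path model.

    Every submodel is sampled from its own equation — in particular, joint
    success is drawn from its probit submodel with team intercepts ``c_j``
    and effect ``lambda_G`` — so the fitted model is exactly the generating
    model.  Returns ``(ModelData, truth)`` where ``truth`` holds the config
    and every unit-level parameter.
    """
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    truth = _draw_individual_truth(cfg, rng)
    s_rows, g_rows, y_rows = [], [], []
    for j in range(cfg.n_teams):
        for t in range(1, cfg.n_trials + 1):
            clicked, _, S, G, D, Y = _trial_events(cfg, truth, j, t, rng, "probit")
            g_rows.append((j, G, D))
            for p in range(2):
                if clicked[p]:
                    i = 2 * j + p
                    s_rows.append((i, j, t, S[p], D))
                    if Y[p] is not None:
                        y_rows.append((i, j, t, Y[p], S[p], G, D))
    data = ModelData.from_rows(
        n_teams=cfg.n_teams,
        s_rows=s_rows,
        g_rows=g_rows,
        y_rows=y_rows,
        n_trials_max=cfg.n_trials,
    )
    truth_out = {"config": asdict(cfg), **{k: v.tolist() for k, v in truth.items()}}
    return data, truth_out


def generate_events(cfg: SyntheticConfig | None = None, seed: int | None = None):
    """Event-level session (trajectory-free) with targets filled.

    Joint success is derived (both players clicked and both correct), so the
    event file is internally consistent: the descriptive pipeline recomputes
    exactly the G used to generate the PAS responses.  Incorrect clicks are
    labelled shadow or static with equal probability.  Click positions are
    synthetic placeholders drawn uniformly on the circle.  Returns
    ``(SessionDataset, truth)``.
    """
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    truth = _draw_individual_truth(cfg, rng)
    world = WorldConfig(trial_duration=cfg.trial_duration)
    teams = []
    for j in range(cfg.n_teams):
        trials = []
        for t in range(1, cfg.n_trials + 1):
            clicked, times, S, G, D, Y = _trial_events(cfg, truth, j, t, rng, "derived")
            clicks, pas = [], []
            for p in range(2):
                if clicked[p]:
                    if S[p]:
                        target = ObjectKind.OTHER_AVATAR
                    else:
                        target = ObjectKind.SHADOW if rng.uniform() < 0.5 else ObjectKind.STATIC
                    clicks.append(
                        ClickEvent(
                            player=p + 1,
                            time=round(times[p], 3),
                            position=round(rng.uniform(0, world.space_length - 0.001), 4),
                            target=target,
                        )
                    )
                    if Y[p] is not None:
                        pas.append(PASResponse(player=p + 1, value=Y[p]))
            trials.append(
                TrialRecord(team_id=j + 1, trial_number=t, clicks=clicks, pas=pas)
            )
        teams.append(TeamRecord(team_id=j + 1, trials=trials))
    ds = SessionDataset(teams=teams, world=world).validate()
    truth_out = {"config": asdict(cfg), **{k: v.tolist() for k, v in truth.items()}}
    return ds, truth_out


# ---------------------------------------------------------------------------
# behavioural level: stochastic search-and-dwell controllers on the torus

def _make_controller(rng, cfg: "BehavioralConfig", tick: float):
    """Sweep until contact; on contact dwell and oscillate; click after
    sustained contact with a per-tick hazard."""
    state = {
        "dir": rng.choice([-1.0, 1.0]),
        "speed": rng.uniform(*cfg.sweep_speed),
        "contact": 0.0,
        "dwell": 0.0,
        "clicked": False,
        "phase": rng.uniform(0, 2 * np.pi),
    }

    def ctrl(history, t):
        s = history[-1]
        click = False
        if s:
            state["contact"] += tick
            state["dwell"] = cfg.dwell_time
            if (
                not state["clicked"]
                and state["contact"] >= cfg.min_contact_s
                and rng.uniform() < cfg.click_hazard * tick
            ):
                click = True
                state["clicked"] = True
            # oscillate around the contacted object
            vel = cfg.dwell_speed * math.sin(2 * np.pi * t / cfg.dwell_period + state["phase"])
            return vel, click
        if state["dwell"] > 0:
            state["dwell"] -= tick
            vel = cfg.dwell_speed * math.sin(2 * np.pi * t / cfg.dwell_period + state["phase"])
            return vel, False
        state["contact"] = max(0.0, state["contact"] - 0.5 * tick)
        return state["dir"] * state["speed"], False

    return ctrl


@dataclass(frozen=True)
class BehavioralConfig:
    """Controller parameters for the behavioural generator (stress-test
    stand-ins, not models of human players)."""

    sweep_speed: tuple[float, float] = (35.0, 75.0)
    dwell_speed: float = 18.0
    dwell_period: float = 1.2
    dwell_time: float = 1.5
    min_contact_s: float = 0.8
    click_hazard: float = 0.8  # per second once contact is sustained


def generate_behavioral(
    cfg: SyntheticConfig | None = None,
    world: WorldConfig | None = None,
    behavior: BehavioralConfig | None = None,
    seed: int | None = None,
):
    """Full-trajectory sessions from the torus simulator.

    Clicks are emitted by the controllers during object contact, so the
    intended target of each click (the nearest felt object at the click
    moment) is known to the generator and stored in the returned truth
    dict under ``intended_targets``; the dataset itself is returned with
    *unassigned* targets so the classification stage can be tested against
    that ground truth.  PAS responses are then drawn from the ordinal
    submodel given the intended outcomes.
    """
    cfg = cfg or SyntheticConfig()
    world = world or WorldConfig(trial_duration=cfg.trial_duration)
    behavior = behavior or BehavioralConfig()
    master = np.random.default_rng(cfg.seed if seed is None else seed)
    truth_ind = _draw_individual_truth(cfg, master)
    teams = []
    intended: dict[str, str] = {}
    for j in range(cfg.n_teams):
        trials = []
        for t in range(1, cfg.n_trials + 1):
            trial_seed = int(master.integers(2**31 - 1))
            crng = np.random.default_rng(trial_seed)
            ctrl_a = _make_controller(crng, behavior, world.tick)
            ctrl_b = _make_controller(crng, behavior, world.tick)
            rec = simulate_trial(
                world,
                ctrl_a,
                ctrl_b,
                seed=trial_seed,
                team_id=j + 1,
                trial_number=t,
            )
            # ground truth: nearest felt object at each click
            S = [None, None]
            for c in rec.clicks:
                p = c.player - 1
                k = int(round(c.time / world.tick))
                from .environment import WorldState

                st = WorldState(
                    avatar=tuple(rec.trajectories[k]),
                    static=rec.static_positions,
                    config=world,
                )
                dists = {
                    kind: torus_distance(rec.trajectories[k, p], pos, world.space_length)
                    for kind, pos in st.felt_objects(p).items()
                }
                kind = min(dists, key=lambda kk: dists[kk])
                intended[f"{j + 1}:{t}:{c.player}"] = kind.value
                S[p] = int(kind == ObjectKind.OTHER_AVATAR)
            both = all(cl is not None for cl in (rec.click_of(1), rec.click_of(2)))
            if both:
                delay = abs(rec.click_of(1).time - rec.click_of(2).time)
                D = int(delay < cfg.delay_window)
            else:
                D = 0
            G = int(both and S[0] == 1 and S[1] == 1)
            pas = []
            for c in rec.clicks:
                p = c.player - 1
                i = 2 * j + p
                eta = (
                    truth_ind["u"][i]
                    + truth_ind["v"][i] * (min(t, truth_ind["tau_P"][i]) - 1.0)
                    + cfg.gamma_S * S[p]
                    + cfg.gamma_G * G
                    + cfg.gamma_D * D
                )
                probs = ordinal_probit_probs(eta, np.asarray(cfg.kappa))
                if crng.uniform() >= cfg.pas_missing_prob:
                    pas.append(
                        PASResponse(player=c.player, value=1 + int(crng.choice(4, p=probs)))
                    )
            rec.pas = pas
            trials.append(rec)
        teams.append(TeamRecord(team_id=j + 1, trials=trials))
    ds = SessionDataset(teams=teams, world=world).validate()
    truth_out = {
        "config": asdict(cfg),
        "intended_targets": intended,
        **{k: v.tolist() for k, v in truth_ind.items()},
    }
    return ds, truth_out
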