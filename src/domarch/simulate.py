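"""Metropolis–Hastings simulation of domain architecture evolution.

States are domain architectures; moves are single-domain gains and losses.
At each iteration one of the ``n + (n+1) N_D`` adjacent states is proposed
(gains are favoured ``N_D``-fold over losses so that all adjacent states are
near-equiprobable) and accepted with probability ``min(1, p(t)/p(s))``,
where the ratio reduces to three smoothed conditionals.  A loss that would
empty the architecture is vetoed, never applied: extinction is forbidden.

Proposal modes
--------------
``paper``
    Gain with probability ``1 - 1/N_D`` (a uniform draw exceeding
    ``1/N_D`` selects a gain), acceptance ``min(1, ratio)``.
``symmetric``
    Gain with probability ``N_D/(N_D+1)``, which makes the forward and
    reverse proposal probabilities of every gain/loss pair exactly equal;
    acceptance still ``min(1, ratio)``.
``exact-hastings``
    The ``symmetric`` proposal with the residual proposal-probability
    ratio folded into acceptance, so detailed balance with respect to the
    first-order architecture distribution holds exactly (for the
    ``symmetric`` proposal the residual is identically 1; it becomes
    nontrivial under ``gain_loss_bias``).

``gain_loss_bias`` multiplies the gain odds in every mode.  Values other
than 1 break the uniform-adjacent-state property and with it the chain's
convergence guarantee; the knob exists for perturbation experiments.

Replicate ``r`` runs on an independent PCG64 stream spawned from
``(seed, r)``, so any single replicate is reproducible in isolation.
Each iteration consumes exactly one block of four uniforms, which makes
:func:`run_chain` bit-identical to repeated calls of :func:`step`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .model import Architecture, FirstOrderModel, as_architecture

ProposalMode = Literal["paper", "symmetric", "exact-hastings"]

_CHUNK = 4096  # uniforms drawn per RNG call in the chain loop


@dataclass(frozen=True)
class SimulationConfig:
    """User-facing simulation parameters (mirrors the JSON config keys)."""

    start: tuple[str, ...] | str = "random-single-domain"
    chain_length: int = 10_000  # T: number of proposed state transitions
    replicates: int = 1
    k: float | str = "default"
    seed: int = 0
    proposal_mode: ProposalMode = "paper"
    gain_loss_bias: float = 1.0
    trace_every: int = 100
    emit_trace: bool = False  # keep the per-iteration event list
    trace_accepted_only: bool = False  # with emit_trace, drop rejected events
    start_weighting: Literal["uniform", "monogram"] = "uniform"
    veto_consumes_iteration: bool = True
    allow_reducible: bool = False

    def __post_init__(self) -> None:
        if self.chain_length < 0:
            raise ValueError("chain_length (T) must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.trace_every < 1:
            raise ValueError("trace_every must be >= 1")
        if self.gain_loss_bias <= 0:
            raise ValueError("gain_loss_bias must be positive")
        if self.proposal_mode not in ("paper", "symmetric", "exact-hastings"):
            raise ValueError(f"unknown proposal mode {self.proposal_mode!r}")


@dataclass(frozen=True)
class ProposalEvent:
    """One attempted gain or loss.

    ``site`` is the 0-based insertion site for gains and the 1-based domain
    position for losses; ``length`` is the pre-move architecture length.
    A vetoed event is a loss proposed from a single-domain architecture.
    """

    iteration: int
    kind: Literal["gain", "loss"]
    site: int
    token: str | None
    ratio: float
    accepted: bool
    vetoed: bool = False
    length: int = 0


@dataclass
class ChainTrace:
    """Diagnostics from one chain: periodic length samples, tallies, events."""

    sampled_lengths: list[tuple[int, int]] = field(default_factory=list)
    sampled_accepts: list[tuple[int, int, int]] = field(default_factory=list)
    events: list[ProposalEvent] | None = None
    tallies: dict[str, int] = field(
        default_factory=lambda: {
            "proposed_gains": 0,
            "proposed_losses": 0,
            "accepted_gains": 0,
            "accepted_losses": 0,
            "vetoed_losses": 0,
        }
    )


def _gain_probability(n_d: int, mode: ProposalMode, bias: float) -> float:
    if mode == "paper":
        odds = bias * (n_d - 1)
    else:  # symmetric / exact-hastings share the proposal law
        odds = bias * n_d
    return odds / (odds + 1.0)


def _log_hastings_corrections(n_d: int, mode: ProposalMode, bias: float) -> tuple[float, float]:
    """Log proposal-ratio corrections (gain, loss) for ``exact-hastings``.

    For a gain from length n, q(s->t) = Pg / ((n+1) N_D) and the reverse
    loss has q(t->s) = Pl / (n+1); the (n+1) factors cancel, leaving the
    length-independent residual Pl N_D / Pg (identically 1 for the
    symmetric proposal at bias 1).
    """
    if mode != "exact-hastings":
        return 0.0, 0.0
    pg = _gain_probability(n_d, "symmetric", bias)
    pl = 1.0 - pg
    corr = math.log(pl * n_d / pg)
    return corr, -corr


def propose(
    state: Sequence[str],
    model: FirstOrderModel,
    rng: np.random.Generator,
    config: SimulationConfig,
) -> tuple[ProposalEvent, Architecture | None]:
    """Draw one uniform gain/loss proposal from ``state``.

    Returns the event (ratio unfilled, accepted False) and the candidate
    architecture, or ``None`` for a vetoed single-domain loss.
    """
    arch = as_architecture(state)
    n = len(arch)
    u = rng.random(4)
    pg = _gain_probability(model.n_d, config.proposal_mode, config.gain_loss_bias)
    if u[0] < pg:
        site = int(u[1] * (n + 1))
        token = model.alphabet.tokens[int(u[2] * model.n_d)]
        event = ProposalEvent(0, "gain", site, token, math.nan, False, length=n)
        return event, arch[:site] + (token,) + arch[site:]
    if n == 1:
        return ProposalEvent(0, "loss", 1, None, math.nan, False, vetoed=True, length=n), None
    pos = int(u[1] * n) + 1
    event = ProposalEvent(0, "loss", pos, None, math.nan, False, length=n)
    return event, arch[: pos - 1] + arch[pos:]


def accept_probability(
    model: FirstOrderModel,
    state: Sequence[str],
    candidate: Sequence[str],
    event: ProposalEvent,
    mode: ProposalMode = "paper",
    gain_loss_bias: float = 1.0,
) -> float:
    """Metropolis–Hastings acceptance probability for one proposed move."""
    from .model import deletion_ratio, insertion_ratio

    arch = as_architecture(state)
    cand = as_architecture(candidate)
    if event.kind == "gain":
        if len(cand) != len(arch) + 1:
            raise ValueError("candidate is not one gain away from state")
        ratio = insertion_ratio(model, arch, event.site, event.token)
    else:
        if len(cand) != len(arch) - 1:
            raise ValueError("candidate is not one loss away from state")
        ratio = deletion_ratio(model, arch, event.site)
    log_cg, log_cl = _log_hastings_corrections(model.n_d, mode, gain_loss_bias)
    corr = math.exp(log_cg if event.kind == "gain" else log_cl)
    return min(1.0, ratio * corr)


def step(
    state: Sequence[str],
    model: FirstOrderModel,
    rng: np.random.Generator,
    config: SimulationConfig,
    trace: ChainTrace | None = None,
    iteration: int = 0,
) -> Architecture:
    """One propose/accept cycle; reference implementation of the chain loop.

    Consumes exactly four uniforms, the same block :func:`run_chain` uses,
    so stepping manually reproduces a chain bit-for-bit.
    """
    arch = as_architecture(state)
    n = len(arch)
    u = rng.random(4)
    pg = _gain_probability(model.n_d, config.proposal_mode, config.gain_loss_bias)
    log_cg, log_cl = _log_hastings_corrections(model.n_d, config.proposal_mode, config.gain_loss_bias)
    table = model.log_conditional_table
    null_id = model.n_d
    ids = [model.alphabet.index(t) for t in arch]

    if u[0] < pg:
        site = int(u[1] * (n + 1))
        tok = int(u[2] * model.n_d)
        left = ids[site - 1] if site > 0 else null_id
        right = ids[site] if site < n else null_id
        num = table[left, tok] + table[tok, right]
        logr = -math.inf if num == -math.inf else num - table[left, right] + log_cg
        accepted = logr >= 0 or math.log(u[3]) < logr
        event = ProposalEvent(
            iteration, "gain", site, model.alphabet.tokens[tok], _safe_exp(logr), accepted, length=n
        )
        new = arch[:site] + (event.token,) + arch[site:] if accepted else arch
    elif n == 1:
        event = ProposalEvent(iteration, "loss", 1, None, 0.0, False, vetoed=True, length=n)
        new = arch
    else:
        pos = int(u[1] * n) + 1
        left = ids[pos - 2] if pos >= 2 else null_id
        right = ids[pos] if pos < n else null_id
        num = table[left, right]
        logr = -math.inf if num == -math.inf else num - table[left, ids[pos - 1]] - table[ids[pos - 1], right] + log_cl
        accepted = logr >= 0 or math.log(u[3]) < logr
        event = ProposalEvent(iteration, "loss", pos, None, _safe_exp(logr), accepted, length=n)
        new = arch[: pos - 1] + arch[pos:] if accepted else arch

    if trace is not None:
        _record(trace, event, config)
    return new


def _safe_exp(logr: float) -> float:
    try:
        return math.exp(logr)
    except OverflowError:
        return math.inf


def _record(trace: ChainTrace, event: ProposalEvent, config: SimulationConfig) -> None:
    t = trace.tallies
    if event.vetoed:
        t["proposed_losses"] += 1
        t["vetoed_losses"] += 1
    elif event.kind == "gain":
        t["proposed_gains"] += 1
        t["accepted_gains"] += event.accepted
    else:
        t["proposed_losses"] += 1
        t["accepted_losses"] += event.accepted
    if config.emit_trace:
        if trace.events is None:
            trace.events = []
        trace.events.append(event)


def run_chain(
    config: SimulationConfig,
    model: FirstOrderModel,
    rng: np.random.Generator | None = None,
    start: Sequence[str] | None = None,
    state_callback=None,
) -> tuple[Architecture, ChainTrace]:
    """Run one chain of ``T = chain_length`` proposed transitions.

    ``start`` overrides ``config.start``; ``state_callback(state)`` (if
    given) is invoked after every iteration with the current state as a
    read-only list of integer token ids (NULL excluded) — used by the
    stationary-distribution checks to tally visited states.
    """
    if not model.is_irreducible and not config.allow_reducible:
        raise ValueError(
            "model has zero conditionals, so the chain is not irreducible; "
            "train with k > 0 or set allow_reducible=True"
        )
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(config.seed)))
    if start is None:
        start = _resolve_start(config, model, rng)
    arch = as_architecture(start)

    table = model.log_conditional_table
    n_d = model.n_d
    null_id = n_d
    tokens = model.alphabet.tokens
    state = [model.alphabet.index(t) for t in arch]
    pg = _gain_probability(n_d, config.proposal_mode, config.gain_loss_bias)
    log_cg, log_cl = _log_hastings_corrections(n_d, config.proposal_mode, config.gain_loss_bias)

    trace = ChainTrace()
    tallies = trace.tallies
    events = [] if config.emit_trace else None
    t_total = config.chain_length
    done = 0
    while done < t_total:
        u = rng.random((min(_CHUNK, t_total - done), 4))
        logu = np.log(u[:, 3])
        for i in range(len(u)):
            if done >= t_total:
                break
            iteration = done + 1
            n = len(state)
            consumed = True
            if u[i, 0] < pg:
                site = int(u[i, 1] * (n + 1))
                tok = int(u[i, 2] * n_d)
                left = state[site - 1] if site > 0 else null_id
                right = state[site] if site < n else null_id
                num = table[left, tok] + table[tok, right]
                logr = -math.inf if num == -math.inf else num - table[left, right] + log_cg
                accepted = logr >= 0 or logu[i] < logr
                tallies["proposed_gains"] += 1
                if accepted:
                    tallies["accepted_gains"] += 1
                    state.insert(site, tok)
                if events is not None and (accepted or not config.trace_accepted_only):
                    events.append(
                        ProposalEvent(iteration, "gain", site, tokens[tok], _safe_exp(logr), accepted, length=n)
                    )
            elif n == 1:
                tallies["proposed_losses"] += 1
                tallies["vetoed_losses"] += 1
                consumed = config.veto_consumes_iteration
                if events is not None and not config.trace_accepted_only:
                    events.append(ProposalEvent(iteration, "loss", 1, None, 0.0, False, True, n))
            else:
                pos = int(u[i, 1] * n)  # 0-based here; reported 1-based
                mid = state[pos]
                left = state[pos - 1] if pos > 0 else null_id
                right = state[pos + 1] if pos < n - 1 else null_id
                num = table[left, right]
                logr = -math.inf if num == -math.inf else num - table[left, mid] - table[mid, right] + log_cl
                accepted = logr >= 0 or logu[i] < logr
                tallies["proposed_losses"] += 1
                if accepted:
                    tallies["accepted_losses"] += 1
                    del state[pos]
                if events is not None and (accepted or not config.trace_accepted_only):
                    events.append(
                        ProposalEvent(iteration, "loss", pos + 1, None, _safe_exp(logr), accepted, length=n)
                    )
            if state_callback is not None:
                state_callback(state)
            if consumed:
                done += 1
                if done % config.trace_every == 0:
                    trace.sampled_lengths.append((done, len(state)))
                    trace.sampled_accepts.append(
                        (done, tallies["accepted_gains"], tallies["accepted_losses"])
                    )
    trace.events = events
    return tuple(tokens[i] for i in state), trace


def _resolve_start(
    config: SimulationConfig, model: FirstOrderModel, rng: np.random.Generator
) -> Architecture:
    if config.start == "random-single-domain":
        if config.start_weighting == "monogram":
            if model.counts is None or not model.counts.monogram:
                raise ValueError("monogram-weighted starts require a count-backed model")
            toks = model.alphabet.tokens
            weights = np.array([model.counts.monogram.get(t, 0) for t in toks], dtype=float)
            cum = np.cumsum(weights / weights.sum())
            return (toks[int(np.searchsorted(cum, rng.random(), side="right"))],)
        return (model.alphabet.tokens[int(rng.random() * model.n_d)],)
    return as_architecture(config.start)


@dataclass
class ReplicateSummary:
    final_lengths: list[int]
    tallies: dict[str, int]

    def as_dict(self) -> dict:
        lengths = np.array(self.final_lengths)
        return {
            "replicates": len(self.final_lengths),
            "mean_final_length": float(lengths.mean()),
            "median_final_length": float(np.median(lengths)),
            "max_final_length": int(lengths.max()),
            "length_distribution": {
                str(k): int(v) for k, v in zip(*np.unique(lengths, return_counts=True))
            },
            "tallies": self.tallies,
        }


def run_replicates(
    config: SimulationConfig,
    model: FirstOrderModel,
    keep_traces: bool = False,
) -> tuple[list[Architecture], ReplicateSummary, list[ChainTrace] | None]:
    """Run ``config.replicates`` independent chains and aggregate.

    Replicate ``r`` uses the PCG64 stream spawned from ``(seed, r)``; with a
    ``random-single-domain`` start each replicate draws its own start token.
    """
    finals: list[Architecture] = []
    traces: list[ChainTrace] = []
    total = {
        "proposed_gains": 0,
        "proposed_losses": 0,
        "accepted_gains": 0,
        "accepted_losses": 0,
        "vetoed_losses": 0,
    }
    for r in range(config.replicates):
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(config.seed, spawn_key=(r,))))
        final, trace = run_chain(config, model, rng=rng)
        finals.append(final)
        for key in total:
            total[key] += trace.tallies[key]
        if keep_traces:
            traces.append(trace)
    summary = ReplicateSummary([len(f) for f in finals], total)
    return finals, summary, traces if keep_traces else None


# -- JSON config -------------------------------------------------------------

_KEY_ALIASES = {"T": "chain_length", "t": "chain_length"}


def config_from_dict(raw: dict) -> SimulationConfig:
    kwargs = {}
    for key, value in raw.items():
        key = _KEY_ALIASES.get(key, key)
        if key == "batch":
            continue
        if key == "start" and isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return SimulationConfig(**kwargs)


def load_configs(path: str | Path) -> list[tuple[str, SimulationConfig]]:
    """Load a JSON config; a ``batch`` block sweeping one variable over a
    list of values expands into one labeled config per value."""
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    base = config_from_dict(raw)
    batch = raw.get("batch")
    if not batch:
        return [("run", base)]
    var = _KEY_ALIASES.get(batch["variable"], batch["variable"])
    return [(f"{var}={v}", replace(base, **{var: v})) for v in batch["values"]]
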