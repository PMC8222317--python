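"""Parameter containers for the change-detection task and the OU observer model.

The task presents a 60 Hz Poisson click train whose underlying rate steps up or
down at an unpredictable time; the observer model tracks a leaky (exponentially
filtered) estimate of the click rate and reports a change when that estimate
crosses a detection bound.  Units follow the field convention: the decision
variable, bounds and drive are expressed in Hz; time constants in seconds;
process noise in Hz per square-root second.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional


BASELINE_RATE = 60.0  # Hz, pre-change generative click rate


class ParameterError(ValueError):
    """Raised when a parameter set violates its domain constraints."""


@dataclass
class TaskConfig:
    """Design of the auditory change-detection task.

    The change time is drawn from an exponential distribution (mean
    ``change_mean``) offset by the ``min_prechange`` baseline period and
    truncated at ``change_max``, which yields a flat change hazard on the
    interval between the two.  Cues are informative ("increase"/"decrease")
    with probability ``p_informed``, otherwise "either".
    """

    baseline_rate: float = BASELINE_RATE
    deltas: tuple = (10.0, 30.0, 50.0)  # magnitudes, signed at draw time
    min_prechange: float = 1.0
    change_mean: float = 3.5
    change_max: float = 7.5
    response_window: float = 0.8
    early_exclusion: float = 0.75
    p_informed: float = 0.5
    p_increase: float = 0.5

    def validate(self) -> "TaskConfig":
        if self.baseline_rate <= 0:
            raise ParameterError("baseline_rate must be positive")
        if not (0 < self.min_prechange <= self.change_max):
            raise ParameterError("need 0 < min_prechange <= change_max")
        if any(abs(d) >= self.baseline_rate for d in self.deltas):
            raise ParameterError("every |delta| must be < baseline_rate")
        if any(d <= 0 for d in self.deltas):
            raise ParameterError("delta magnitudes must be positive")
        for p in (self.p_informed, self.p_increase):
            if not 0.0 <= p <= 1.0:
                raise ParameterError("probabilities must lie in [0, 1]")
        if self.response_window <= 0:
            raise ParameterError("response_window must be positive")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["deltas"] = list(self.deltas)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        d = dict(d)
        if "deltas" in d:
            d["deltas"] = tuple(float(x) for x in d["deltas"])
        return cls(**d).validate()


@dataclass
class ModelParams:
    """Parameters of one OU decision process (one detection direction).

    tau
        Width of the exponential evidence filter (s); the timescale over
        which past clicks influence the decision variable.
    bound_up, bound_down
        Sticky (absorbing) detection bounds in Hz.  An increase detector has
        only ``bound_up``; a decrease detector only ``bound_down``.
    sigma_process
        Diffusion coefficient of the decision variable (Hz * s**-0.5).
    ndt_mean, ndt_sd
        Gaussian non-decision time (s): sensory plus motor latency added to
        the bound-crossing time.
    depression_enabled, dep_scale, dep_tau
        Short-term input depression: each click's magnitude is multiplied by
        the current adaptation state, after which the state is scaled by
        ``dep_scale`` and relaxes back to 1 with time constant ``dep_tau``.
    """

    tau: float = 0.4
    bound_up: Optional[float] = None
    bound_down: Optional[float] = None
    sigma_process: float = 15.0
    ndt_mean: float = 0.35
    ndt_sd: float = 0.06
    depression_enabled: bool = False
    dep_scale: float = 0.45
    dep_tau: float = 0.02

    def validate(self, baseline: float = BASELINE_RATE) -> "ModelParams":
        if self.tau <= 0:
            raise ParameterError("tau must be positive")
        if self.sigma_process < 0:
            raise ParameterError("sigma_process must be >= 0")
        if self.ndt_sd <= 0:
            raise ParameterError("ndt_sd must be positive")
        if self.bound_up is None and self.bound_down is None:
            raise ParameterError("at least one bound is required")
        if self.bound_up is not None and self.bound_down is not None:
            if self.bound_down >= self.bound_up:
                raise ParameterError("bound_down must lie below bound_up")
            if not (self.bound_down < baseline < self.bound_up):
                raise ParameterError(
                    "baseline fixed point must lie between the bounds"
                )
        if not (0 < self.dep_scale <= 1):
            raise ParameterError("dep_scale must lie in (0, 1]")
        if self.dep_tau <= 0:
            raise ParameterError("dep_tau must be positive")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d).validate()


@dataclass
class ObserverParams:
    """Ground-truth observer: one single-bound process per cue x direction.

    Under an informative cue the observer runs the matching single process;
    under the uninformative cue both uninformed processes run on the same
    click train with independent noise and the first bound crossing wins.

    Default bounds place the informed increase bound (78.3 Hz) below the
    uninformed one (83.9 Hz), the ordering recovered from pooled human data;
    filter widths default to a longer timescale for increase detection
    (0.4 s) than decrease detection (0.15 s).  Process noise and the
    non-decision time are set to values that give this synthetic observer
    hit, false-alarm, and reaction-time statistics in the range human
    subjects produce on this task (see docs/methods.md).
    """

    informed_increase: ModelParams = field(
        default_factory=lambda: ModelParams(tau=0.4, bound_up=78.3, sigma_process=4.0)
    )
    informed_decrease: ModelParams = field(
        default_factory=lambda: ModelParams(tau=0.15, bound_down=28.0, sigma_process=4.0)
    )
    uninformed_increase: ModelParams = field(
        default_factory=lambda: ModelParams(tau=0.4, bound_up=83.9, sigma_process=4.0)
    )
    uninformed_decrease: ModelParams = field(
        default_factory=lambda: ModelParams(tau=0.15, bound_down=24.0, sigma_process=4.0)
    )

    def validate(self) -> "ObserverParams":
        for name in ("informed_increase", "uninformed_increase"):
            p = getattr(self, name)
            p.validate()
            if p.bound_up is None or p.bound_down is not None:
                raise ParameterError(f"{name} must have only an upper bound")
        for name in ("informed_decrease", "uninformed_decrease"):
            p = getattr(self, name)
            p.validate()
            if p.bound_down is None or p.bound_up is not None:
                raise ParameterError(f"{name} must have only a lower bound")
        return self

    def to_dict(self) -> dict:
        return {k: v.to_dict() for k, v in asdict(self).items()}

    @classmethod
    def from_dict(cls, d: dict) -> "ObserverParams":
        return cls(**{k: ModelParams(**v) for k, v in d.items()}).validate()


@dataclass
class SolverConfig:
    """Numerical settings of the Fokker-Planck propagation.

    dt is the propagation step of the discretized solution; the decision
    variable distribution lives on a uniform grid of ``n_grid`` points.
    Bounds are inactive for the first ``pre_bound_time`` seconds, matching
    the task's guaranteed no-change period at stimulus onset.
    """

    dt: float = 0.02
    n_substeps: int = 1   # propagation substeps per input bin
    n_grid: int = 501
    pre_bound_time: float = 0.8
    likelihood_window: float = 0.1  # half-width (s) of the RT window sum
    likelihood_floor: float = 1e-10
    kernel_halfwidth_sd: float = 4.5  # Gaussian step kernel support, in SDs
    ndt_halfwidth_sd: float = 5.0
    dep_quantum: float = 0.25  # quantization of depressed click counts

    def validate(self) -> "SolverConfig":
        if self.dt <= 0 or self.dt > 0.05:
            raise ParameterError("dt must lie in (0, 0.05] s")
        if self.n_substeps < 1:
            raise ParameterError("n_substeps must be >= 1")
        if self.n_grid < 51:
            raise ParameterError("n_grid too small for a meaningful solution")
        if self.pre_bound_time < 0:
            raise ParameterError("pre_bound_time must be >= 0")
        return self
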