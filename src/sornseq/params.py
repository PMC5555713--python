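"""Model constants for the self-organizing recurrent network (SORN).

All scalar parameters of the network live in :class:`SornParams`.  The defaults
are the single parameter set used for every experiment: a reservoir of 300
binary excitatory units with 20% as many inhibitory units, sparse random
excitatory connectivity, and three plasticity rules (STDP, synaptic
normalization, intrinsic plasticity) plus a delta-rule readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict


class ConfigurationError(ValueError):
    """Raised when parameters or a config file violate an invariant."""


@dataclass
class SornParams:
    """Scalar constants of the SORN model.

    Parameters
    ----------
    n_excitatory : int
        Number of excitatory reservoir units (N_E).
    n_inhibitory : int, optional
        Number of inhibitory units (N_I).  Defaults to ``round(0.2 * n_excitatory)``.
    t_max_e, t_max_i : float
        Upper bounds of the uniform distributions from which the initial
        excitatory / inhibitory thresholds are drawn.
    p_connect : float
        Probability of each possible excitatory-to-excitatory synapse existing.
    n_input_per_symbol : int
        Number of input units dedicated to each input symbol (N_input).
    eta_stdp : float
        Learning rate of spike-timing dependent plasticity.
    eta_ip : float
        Learning rate of intrinsic (threshold) plasticity.
    h_ip : float
        Target firing rate of each excitatory unit under intrinsic plasticity.
    mu_readout : float
        Delta-rule learning rate of the linear readout.
    seed : int, optional
        Seed for the run's random stream.
    """

    n_excitatory: int = 300
    n_inhibitory: int | None = None
    t_max_e: float = 0.5
    t_max_i: float = 0.9
    p_connect: float = 0.1
    n_input_per_symbol: int = 10
    eta_stdp: float = 1e-4
    eta_ip: float = 0.002
    h_ip: float = 0.1
    mu_readout: float = 2e-5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_inhibitory is None:
            self.n_inhibitory = int(round(0.2 * self.n_excitatory))
        self.validate()

    def validate(self) -> None:
        for name in ("n_excitatory", "n_inhibitory", "n_input_per_symbol"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v <= 0:
                raise ConfigurationError(f"{name} must be a positive integer, got {v!r}")
        for name in ("p_connect", "h_ip"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigurationError(f"{name} must lie in (0, 1], got {v!r}")
        for name in ("t_max_e", "t_max_i", "eta_stdp", "eta_ip", "mu_readout"):
            v = getattr(self, name)
            if v < 0:
                raise ConfigurationError(f"{name} must be non-negative, got {v!r}")
        if self.seed is not None and (not isinstance(self.seed, int) or self.seed < 0):
            raise ConfigurationError(f"seed must be a non-negative integer, got {self.seed!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SornParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)
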