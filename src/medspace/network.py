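"""Random mediator-explicit interaction networks.

A community blueprint consists of three sparse random matrices over
``n_species`` species and ``n_mediators`` diffusible mediators:

* ``beta[j, i]``  — production rate of mediator j by species i
  (fmol per cell per hour); a production link exists with probability
  ``qp`` per (mediator, species) pair.
* ``rho[i, j]``   — signed influence of mediator j on the growth rate of
  species i (1/hr at saturation); an influence link exists with
  probability ``qc``, its magnitude is uniform on (0, rint0] and its
  sign is facilitative with probability ``fac_ratio``.
* ``alpha[j, i]`` — consumption rate (fmol per cell per hour); a species
  consumes a mediator exactly when that mediator influences it,
  regardless of the sign of the influence.

Link rates are uniform between 0.5x and 1.5x their set value.  Each
random component draws from its own child stream of the seed, so two
networks generated from the same seed with different ``fac_ratio``
differ only in the signs of their influences (common random numbers
across swept conditions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._exceptions import ParameterError

__all__ = [
    "InteractionNetwork",
    "generate_network",
    "scale_self_facilitation",
    "count_self_facilitation",
]


@dataclass(frozen=True)
class InteractionNetwork:
    """A random community blueprint.

    Attributes
    ----------
    rho : ndarray, shape (n_species, n_mediators)
        Signed influence of each mediator on each species' growth rate,
        1/hr at saturation; zero where there is no influence link.
    beta : ndarray, shape (n_mediators, n_species)
        Production rates, fmol per cell per hour; zero where no link.
    alpha : ndarray, shape (n_mediators, n_species)
        Consumption rates; nonzero exactly where ``rho.T`` is nonzero.
    r0 : ndarray, shape (n_species,)
        Basal growth rate of each species in isolation, 1/hr.
    seed : tuple
        Entropy the network was generated from (empty for hand-built
        networks).
    """

    rho: np.ndarray
    beta: np.ndarray
    alpha: np.ndarray
    r0: np.ndarray
    seed: tuple = field(default=())

    def __post_init__(self):
        rho = np.asarray(self.rho, dtype=float)
        beta = np.asarray(self.beta, dtype=float)
        alpha = np.asarray(self.alpha, dtype=float)
        r0 = np.asarray(self.r0, dtype=float)
        object.__setattr__(self, "rho", rho)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "r0", r0)
        object.__setattr__(self, "seed", tuple(np.atleast_1d(self.seed)
                                               .astype(object))
                           if np.size(self.seed) else ())
        nc, nm = rho.shape
        if beta.shape != (nm, nc) or alpha.shape != (nm, nc):
            raise ParameterError(
                f"inconsistent matrix shapes: rho {rho.shape}, "
                f"beta {beta.shape}, alpha {alpha.shape}")
        if r0.shape != (nc,):
            raise ParameterError(f"r0 must have shape ({nc},)")
        if (beta < 0).any() or (alpha < 0).any():
            raise ParameterError("beta and alpha must be nonnegative")
        if ((alpha.T > 0) != (rho != 0)).any():
            raise ParameterError(
                "consumption links must coincide with influence links")

    @property
    def n_species(self) -> int:
        return self.rho.shape[0]

    @property
    def n_mediators(self) -> int:
        return self.rho.shape[1]

    def __eq__(self, other):
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return (np.array_equal(self.rho, other.rho)
                and np.array_equal(self.beta, other.beta)
                and np.array_equal(self.alpha, other.alpha)
                and np.array_equal(self.r0, other.r0))

    # -- serialization (self-describing JSON; float repr round-trips
    #    exactly in Python) --------------------------------------------

    def to_json(self) -> str:
        payload = {
            "format": "medspace.network/1",
            "n_species": self.n_species,
            "n_mediators": self.n_mediators,
            "seed": [int(s) for s in self.seed],
            "rho": self.rho.tolist(),
            "beta": self.beta.tolist(),
            "alpha": self.alpha.tolist(),
            "r0": self.r0.tolist(),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "InteractionNetwork":
        d = json.loads(text)
        if d.get("format") != "medspace.network/1":
            raise ParameterError("not a medspace network file")
        return cls(rho=np.array(d["rho"], dtype=float),
                   beta=np.array(d["beta"], dtype=float),
                   alpha=np.array(d["alpha"], dtype=float),
                   r0=np.array(d["r0"], dtype=float),
                   seed=tuple(d.get("seed", ())))

    def save(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "InteractionNetwork":
        with open(path) as fh:
            return cls.from_json(fh.read())


def generate_network(n_species: int = 10,
                     n_mediators: int = 5,
                     qp: float = 0.5,
                     qc: float = 0.5,
                     fac_ratio: float = 0.5,
                     beta0: float = 0.1,
                     alpha0: float = 0.15,
                     rint0: float = 0.2,
                     r0_range: tuple = (0.1, 0.2),
                     seed=0) -> InteractionNetwork:
    """Draw a random interaction network.

    Parameters
    ----------
    qp : float
        Probability that a given species produces a given mediator.
    qc : float
        Probability that a given mediator influences (and is consumed
        by) a given species.
    fac_ratio : float
        Probability that a present influence is facilitative (positive);
        a fac:inh ratio of 90:10 corresponds to ``fac_ratio=0.9``.
    beta0, alpha0 : float
        Set values of the production and consumption rates; realized
        rates are uniform on [0.5*v, 1.5*v].
    rint0 : float
        Maximum influence magnitude (1/hr); magnitudes are uniform on
        (0, rint0].
    r0_range : (float, float)
        Uniform range of basal growth rates (1/hr).
    seed : int or sequence of int
        Entropy for the network's random stream.

    Returns
    -------
    InteractionNetwork
        Deterministic given ``seed`` and the parameters.
    """
    for name, p in (("qp", qp), ("qc", qc), ("fac_ratio", fac_ratio)):
        if not 0.0 <= p <= 1.0:
            raise ParameterError(f"{name}={p} must be a probability in [0,1]")
    for name, v in (("beta0", beta0), ("alpha0", alpha0), ("rint0", rint0)):
        if not v > 0:
            raise ParameterError(f"{name}={v} must be positive")
    lo, hi = r0_range
    if not (0 < lo <= hi):
        raise ParameterError(f"invalid r0_range {r0_range}")
    if n_species < 1 or n_mediators < 1:
        raise ParameterError("need at least one species and one mediator")

    entropy = [int(s) for s in np.atleast_1d(seed)]
    ss = np.random.SeedSequence(entropy)
    # one child stream per random component so that changing a single
    # generation parameter perturbs only the draws it governs
    (s_plink, s_prate, s_ilink, s_imag,
     s_isign, s_crate, s_r0) = ss.spawn(7)

    nm, nc = n_mediators, n_species
    u = np.random.default_rng
    prod_mask = u(s_plink).random((nm, nc)) < qp
    beta = np.where(prod_mask, beta0 * (0.5 + u(s_prate).random((nm, nc))),
                    0.0)
    infl_mask = u(s_ilink).random((nc, nm)) < qc
    # magnitude uniform on (0, rint0]: 1-U with U in [0,1) avoids exact 0,
    # which would break the consumption/influence coupling
    mag = rint0 * (1.0 - u(s_imag).random((nc, nm)))
    sign = np.where(u(s_isign).random((nc, nm)) < fac_ratio, 1.0, -1.0)
    rho = np.where(infl_mask, sign * mag, 0.0)
    alpha = np.where(infl_mask.T,
                     alpha0 * (0.5 + u(s_crate).random((nm, nc))), 0.0)
    r0 = lo + (hi - lo) * u(s_r0).random(nc)
    return InteractionNetwork(rho=rho, beta=beta, alpha=alpha, r0=r0,
                              seed=tuple(entropy))


def _self_facilitation_mask(network: InteractionNetwork) -> np.ndarray:
    """(species, mediator) pairs where a species produces a mediator
    that facilitates its own growth."""
    return (network.beta.T > 0) & (network.rho > 0)


def scale_self_facilitation(network: InteractionNetwork,
                            factor: float) -> InteractionNetwork:
    """Weaken self-facilitation links by a multiplicative factor.

    Every influence ``rho[i, j]`` where species i both produces
    mediator j and is positively influenced by it is multiplied by
    ``factor``; all other entries are untouched.  Consumption links are
    preserved (the influence stays nonzero for factor > 0; for
    factor = 0 the consumption link is removed with it to keep the
    support coupling).
    """
    if not 0.0 <= factor <= 1.0:
        raise ParameterError(f"factor={factor} must be in [0, 1]")
    mask = _self_facilitation_mask(network)
    rho = np.where(mask, network.rho * factor, network.rho)
    alpha = network.alpha
    if factor == 0.0:
        alpha = np.where(mask.T, 0.0, alpha)
    return InteractionNetwork(rho=rho, beta=network.beta, alpha=alpha,
                              r0=network.r0, seed=network.seed)


def count_self_facilitation(network: InteractionNetwork) -> int:
    """Number of (species, mediator) self-facilitation pairs."""
    return int(_self_facilitation_mask(network).sum())
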