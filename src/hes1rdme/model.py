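"""The Hes1 negative-feedback reaction network as per-voxel stochastic channels.

The network couples four species — hes1 mRNA, Hes1 protein, and the two
promoter states ``P_f`` (free) and ``P_o`` (occupied by Hes1 protein) —
through seven elementary mass-action channels:

====  =========================================  ==================  =============
  #   channel                                    localization        propensity
====  =========================================  ==================  =============
  1   P_f + protein -> P_o   (binding)           gene voxel          c1·x_prot·x_Pf
  2   P_o -> P_f + protein   (unbinding)         gene voxel          k2·x_Po
  3   P_f -> P_f + mRNA      (basal txn)         gene voxel          alpha_m·x_Pf
  4   P_o -> P_o + mRNA      (repressed txn)     gene voxel          (alpha_m/gamma)·x_Po
  5   mRNA -> mRNA + protein (translation)       cytoplasm voxels    alpha_p·x_mRNA
  6   mRNA -> 0              (mRNA decay)        every voxel         mu_m·x_mRNA
  7   protein -> 0           (protein decay)     every voxel         mu_p·x_prot
====  =========================================  ==================  =============

The feedback is negative because the occupied promoter transcribes ``gamma``
times slower than the free one; the loop is closed spatially — mRNA made in
the gene voxel must diffuse into the cytoplasm to be translated, and protein
must diffuse back to the promoter to repress it.  Protein bound to the
promoter (``P_o``) is a distinct species: it is protected from degradation
and is returned intact by unbinding, so every channel conserves
``P_f + P_o``.

``k1`` is quoted in molar units (M⁻¹ min⁻¹) as binding rates are measured;
in a discrete-copy-number voxel of volume ``V`` the per-pair stochastic rate
is ``k1 / (N_A · V)`` with ``V`` in litres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np
import yaml
from scipy.constants import Avogadro

from .geometry import ConfigurationError, Mesh

__all__ = [
    "SPECIES",
    "MRNA",
    "PROTEIN",
    "PF",
    "PO",
    "ParameterSet",
    "ReactionChannel",
    "ReactionSystem",
    "SystemState",
    "convert_bimolecular_rate",
    "build_reaction_system",
    "initial_state",
]

logger = logging.getLogger(__name__)

SPECIES = ("mRNA", "protein", "P_f", "P_o")
MRNA, PROTEIN, PF, PO = 0, 1, 2, 3

LITRES_PER_UM3 = 1.0e-15


@dataclass(frozen=True)
class ParameterSet:
    """Rate constants and geometry parameters of the Hes1 model.

    Defaults are the baseline values used throughout: promoter binding
    ``k1`` (M⁻¹ min⁻¹) and unbinding ``k2`` (min⁻¹); basal transcription
    ``alpha_m`` (min⁻¹) with repression factor ``gamma`` (the occupied
    promoter transcribes at ``alpha_m / gamma``); translation ``alpha_p``
    (min⁻¹ per mRNA); degradation rates ``mu_m`` and ``mu_p`` (min⁻¹);
    a common diffusion coefficient ``D`` (m² min⁻¹) for mRNA and protein;
    and the promoter depth ``r`` (μm inward from the nuclear membrane).
    """

    k1: float = 1.00e9
    k2: float = 0.1
    alpha_m: float = 3.00
    gamma: float = 30.00
    alpha_p: float = 1.00
    mu_m: float = 0.015
    mu_p: float = 0.043
    D: float = 6.00e-13
    r: float = 3.0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ConfigurationError(f"parameter {f.name} must be >= 0, got {v}")
        if self.gamma < 1:
            raise ConfigurationError(f"gamma must be >= 1, got {self.gamma}")

    def with_overrides(self, **kwargs) -> "ParameterSet":
        for k, v in kwargs.items():
            logger.info("parameter override: %s = %s", k, v)
        return replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown parameter names: {sorted(unknown)}")
        return cls().with_overrides(**d)

    @classmethod
    def from_file(cls, path) -> "ParameterSet":
        """Read parameters from a YAML file; keys under ``parameters:`` or top-level."""
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc.get("parameters", doc))

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def convert_bimolecular_rate(k1: float, voxel_volume: float) -> float:
    """Molar bimolecular rate -> per-reactant-pair stochastic rate (min⁻¹).

    ``k1`` in M⁻¹ min⁻¹, ``voxel_volume`` in μm³; returns
    ``k1 / (N_A · V_litres)``.  The binding propensity in the gene voxel is
    this value times ``x_protein · x_Pf``.
    """
    if voxel_volume <= 0:
        raise ConfigurationError(f"voxel volume must be positive, got {voxel_volume}")
    if k1 < 0:
        raise ConfigurationError(f"k1 must be >= 0, got {k1}")
    return k1 / (Avogadro * voxel_volume * LITRES_PER_UM3)


@dataclass
class ReactionChannel:
    """One mass-action channel: stoichiometry, reactants and per-voxel rates.

    ``reactants`` holds up to two species indices (second is -1 for
    first-order channels); the propensity in voxel ``v`` is
    ``rate_per_voxel[v]`` times the product of the reactant copy numbers.
    """

    name: str
    stoichiometry: np.ndarray  # (len(SPECIES),) int
    reactants: tuple  # (s1, s2) with s2 == -1 for first-order
    rate_per_voxel: np.ndarray  # (V,) float, zero where channel is absent


@dataclass
class ReactionSystem:
    """The seven Hes1 channels instantiated on a mesh."""

    species: tuple
    channels: list
    mesh: Mesh
    params: ParameterSet

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def stoichiometric_matrix(self) -> np.ndarray:
        """(S, R) matrix whose columns are the channel state changes."""
        return np.stack([c.stoichiometry for c in self.channels], axis=1)

    def propensities(self, counts: np.ndarray) -> np.ndarray:
        """(V, R) propensity of every channel in every voxel for state ``counts``."""
        V = self.mesh.n_voxels
        a = np.empty((V, self.n_channels))
        for r, ch in enumerate(self.channels):
            s1, s2 = ch.reactants
            f = counts[:, s1].astype(float)
            if s2 >= 0:
                f = f * counts[:, s2]
            a[:, r] = ch.rate_per_voxel * f
        return a


def build_reaction_system(
    params: ParameterSet, mesh: Mesh, well_mixed: bool = False
) -> ReactionSystem:
    """Instantiate the seven channels with their subcellular localization.

    With ``well_mixed=True`` the localization predicates are dropped
    (translation allowed in every voxel); this reduction is only meaningful
    on a single-voxel mesh, where it reproduces the classical well-stirred
    model for cross-validation against a Gillespie direct-method sampler.
    """
    V = mesh.n_voxels
    g = mesh.gene_voxel
    c1 = convert_bimolecular_rate(params.k1, float(mesh.voxel_volumes[g]))

    def local(rate: float, where: str) -> np.ndarray:
        out = np.zeros(V)
        if where == "gene":
            out[g] = rate
        elif where == "cytoplasm":
            if well_mixed:
                out[:] = rate
            else:
                out[mesh.cytoplasm_mask] = rate
        else:  # everywhere
            out[:] = rate
        return out

    sto = lambda **kw: np.array(
        [kw.get("mRNA", 0), kw.get("protein", 0), kw.get("P_f", 0), kw.get("P_o", 0)],
        dtype=np.int64,
    )

    channels = [
        ReactionChannel(
            "binding", sto(protein=-1, P_f=-1, P_o=+1), (PROTEIN, PF), local(c1, "gene")
        ),
        ReactionChannel(
            "unbinding", sto(protein=+1, P_f=+1, P_o=-1), (PO, -1), local(params.k2, "gene")
        ),
        ReactionChannel(
            "transcription", sto(mRNA=+1), (PF, -1), local(params.alpha_m, "gene")
        ),
        ReactionChannel(
            "repressed_transcription",
            sto(mRNA=+1),
            (PO, -1),
            local(params.alpha_m / params.gamma, "gene"),
        ),
        ReactionChannel(
            "translation", sto(protein=+1), (MRNA, -1), local(params.alpha_p, "cytoplasm")
        ),
        ReactionChannel(
            "mrna_degradation", sto(mRNA=-1), (MRNA, -1), local(params.mu_m, "everywhere")
        ),
        ReactionChannel(
            "protein_degradation",
            sto(protein=-1),
            (PROTEIN, -1),
            local(params.mu_p, "everywhere"),
        ),
    ]
    return ReactionSystem(species=SPECIES, channels=channels, mesh=mesh, params=params)


@dataclass
class SystemState:
    """Copy numbers per voxel and species at a time point."""

    counts: np.ndarray  # (V, S) int64
    t: float = 0.0

    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def copy(self) -> "SystemState":
        return SystemState(self.counts.copy(), self.t)


def initial_state(
    mesh: Mesh,
    seed: Optional[int] = None,
    n_protein: int = 60,
    n_mrna: int = 10,
) -> SystemState:
    """Baseline initial condition: proteins uniform in the cytoplasm, mRNA
    uniform in the nucleus, one free promoter in the gene voxel.

    "Uniform" means uniform in space: molecules are multinomially distributed
    over the subdomain's voxels with probabilities proportional to voxel
    volume.  On a mesh lacking one of the compartments (e.g. a single-voxel
    mesh) the molecules fall back to the whole mesh.
    """
    rng = np.random.default_rng(seed)
    counts = np.zeros((mesh.n_voxels, len(SPECIES)), dtype=np.int64)

    def place(n: int, mask: np.ndarray, s: int) -> None:
        if not mask.any():
            mask = np.ones(mesh.n_voxels, dtype=bool)
        idx = np.flatnonzero(mask)
        w = mesh.voxel_volumes[idx]
        counts[idx, s] += rng.multinomial(n, w / w.sum())

    place(n_protein, mesh.cytoplasm_mask, PROTEIN)
    place(n_mrna, mesh.nucleus_mask, MRNA)
    counts[mesh.gene_voxel, PF] = 1
    return SystemState(counts=counts, t=0.0)
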