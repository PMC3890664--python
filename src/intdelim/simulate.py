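"""Synthetic ("virtual species") data with the structure the analysis assumes.

The generator produces, for a set of taxon specifications:

* binary characters as independent Bernoulli draws at per-taxon state-1
  frequencies (the measurement model behind the discrete matrix);
* continuous characters as Normal(mu, sigma) draws, meristic characters
  rounded to the nearest integer;
* smooth climate layers (linear gradient + sinusoid + Gaussian noise);
* occurrence records sampled without replacement across grid cells with
  probability proportional to a Gaussian suitability surface
  prod_l exp(-(value_l - optimum_l)^2 / (2 breadth_l^2));
* a rooted tree of balanced per-taxon clades with a configurable
  discordance probability of regrafting tips across clades.

Everything is reproducible given a seed, and every generated dataset
passes the package's reader validations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .datatypes import (
    CharacterMatrix,
    ClimateStack,
    OccurrenceSet,
    TaxonTree,
    ValidationError,
)

__all__ = ["TaxonSpec", "WorldSpec", "gen_characters", "gen_world",
           "gen_occurrences", "gen_tree", "true_suitability"]


@dataclass
class TaxonSpec:
    """Ground-truth parameters of one synthetic taxon.

    ``discrete`` maps character name -> true state-1 frequency;
    ``continuous`` maps character name -> (mu, sigma); ``meristic``
    lists continuous characters to round to integers; ``niche`` maps
    layer name -> (optimum, breadth).
    """

    name: str
    n_females: int = 15
    n_males: int = 15
    discrete: dict = field(default_factory=dict)
    continuous: dict = field(default_factory=dict)
    meristic: Sequence[str] = ()
    niche: dict = field(default_factory=dict)
    n_occurrences: int = 25
    n_tips: int = 4

    def __post_init__(self) -> None:
        for ch, f in self.discrete.items():
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"{self.name}/{ch}: frequency must be in [0,1]")
        for ch, (_, sd) in self.continuous.items():
            if sd < 0:
                raise ValidationError(f"{self.name}/{ch}: sigma must be >= 0")
        for layer, (_, breadth) in self.niche.items():
            if breadth <= 0:
                raise ValidationError(f"{self.name}/{layer}: breadth must be > 0")


@dataclass
class WorldSpec:
    """Synthetic climate world: grid geometry plus layer construction.

    Each layer is ``gradient_amplitude`` times a linear gradient in a
    per-layer direction, plus ``sine_amplitude`` times a sinusoidal
    term, plus Normal(0, ``noise_sd``) cell noise — smooth enough to
    exercise the envelope machinery without a full spatial
    autocorrelation model.
    """

    nrows: int = 25
    ncols: int = 25
    n_layers: int = 3
    xllcorner: float = -75.0
    yllcorner: float = -15.0
    cellsize: float = 0.05
    gradient_amplitude: float = 10.0
    sine_amplitude: float = 2.0
    noise_sd: float = 0.5
    seed: int = 0


def gen_characters(specs: Sequence[TaxonSpec], seed: int = 0
                   ) -> tuple[CharacterMatrix, pd.DataFrame]:
    """Generate the discrete matrix and raw continuous measurements.

    Returns (CharacterMatrix, raw DataFrame with columns id, taxon, sex
    then one column per continuous character).
    """
    if len(specs) < 2:
        raise ValidationError("gen_characters needs >= 2 taxa")
    rng = np.random.default_rng(seed)
    disc_chars = sorted({ch for s in specs for ch in s.discrete})
    cont_chars = sorted({ch for s in specs for ch in s.continuous})
    disc_rows, cont_rows = [], []
    for s in specs:
        n = s.n_females + s.n_males
        ids = [f"{s.name}_{i + 1}" for i in range(n)]
        sexes = ["female"] * s.n_females + ["male"] * s.n_males
        block = {"id": ids, "taxon": [s.name] * n, "sex": sexes,
                 "age_class": ["adult"] * n}
        for ch in disc_chars:
            if ch in s.discrete:
                block[ch] = rng.binomial(1, s.discrete[ch], size=n).astype(float)
            else:
                block[ch] = [np.nan] * n
        disc_rows.append(pd.DataFrame(block))
        raw = {"id": ids, "taxon": [s.name] * n, "sex": sexes}
        for ch in cont_chars:
            if ch in s.continuous:
                mu, sd = s.continuous[ch]
                vals = rng.normal(mu, sd, size=n)
                if ch in s.meristic:
                    vals = np.round(vals)
                raw[ch] = vals
            else:
                raw[ch] = [np.nan] * n
        cont_rows.append(pd.DataFrame(raw))
    matrix = CharacterMatrix(pd.concat(disc_rows, ignore_index=True), {})
    return matrix, pd.concat(cont_rows, ignore_index=True)


def gen_world(world: WorldSpec) -> ClimateStack:
    """Generate a smooth, fully valid climate stack."""
    rng = np.random.default_rng(world.seed)
    rows, cols = np.meshgrid(
        np.arange(world.nrows), np.arange(world.ncols), indexing="ij"
    )
    u = cols / max(1, world.ncols - 1)
    v = rows / max(1, world.nrows - 1)
    layers = []
    for k in range(world.n_layers):
        theta = 2 * np.pi * k / world.n_layers
        grad = np.cos(theta) * u + np.sin(theta) * v
        sine = np.sin(2 * np.pi * (u + 0.37 * k)) * np.cos(2 * np.pi * (v - 0.19 * k))
        noise = rng.normal(0.0, world.noise_sd, size=grad.shape)
        layers.append(
            world.gradient_amplitude * grad + world.sine_amplitude * sine + noise
        )
    return ClimateStack(
        names=[f"layer{k + 1}" for k in range(world.n_layers)],
        values=np.stack(layers),
        xllcorner=world.xllcorner,
        yllcorner=world.yllcorner,
        cellsize=world.cellsize,
    )


def true_suitability(spec: TaxonSpec, stack: ClimateStack) -> np.ndarray:
    """Ground-truth Gaussian suitability of each cell for one taxon."""
    suit = np.ones(stack.shape)
    for layer, (opt, breadth) in spec.niche.items():
        if layer not in stack.names:
            raise ValidationError(f"{spec.name}: unknown layer {layer!r}")
        values = stack.values[stack.names.index(layer)]
        suit *= np.exp(-((values - opt) ** 2) / (2.0 * breadth**2))
    return np.where(stack.mask, suit, 0.0)


def gen_occurrences(spec: TaxonSpec, stack: ClimateStack, seed: int = 0) -> OccurrenceSet:
    """Sample occurrence cells without replacement, p proportional to
    true suitability; coordinates are cell centers (so per-cell
    deduplication is a no-op by construction)."""
    rng = np.random.default_rng(seed)
    suit = true_suitability(spec, stack)
    flat = suit.ravel()
    available = np.flatnonzero(flat > 0)
    if spec.n_occurrences > len(available):
        raise ValidationError(
            f"{spec.name}: requested {spec.n_occurrences} occurrences but only "
            f"{len(available)} cells have positive suitability"
        )
    p = flat[available] / flat[available].sum()
    chosen = rng.choice(available, size=spec.n_occurrences, replace=False, p=p)
    ncols = stack.shape[1]
    coords = [stack.cell_center(idx // ncols, idx % ncols) for idx in chosen]
    return OccurrenceSet(taxon=spec.name, records=np.array(coords))


def _clade_newick(tips: Sequence[str]) -> str:
    out = tips[0]
    for t in tips[1:]:
        out = f"({out},{t})"
    return out


def gen_tree(specs: Sequence[TaxonSpec], discordance: float = 0.0,
             seed: int = 0) -> TaxonTree:
    """Balanced per-taxon clades; each tip is regrafted into a random
    other clade with probability ``discordance``, breaking exclusivity."""
    if not 0.0 <= discordance <= 1.0:
        raise ValidationError("discordance must be in [0,1]")
    rng = np.random.default_rng(seed)
    clades = {s.name: [f"{s.name}_t{i + 1}" for i in range(s.n_tips)] for s in specs}
    assignments = {tip: name for name, tips in clades.items() for tip in tips}
    if discordance > 0:
        names = list(clades)
        for tip, home in list(assignments.items()):
            if len(clades[home]) > 1 and rng.random() < discordance:
                others = [n for n in names if n != home]
                target = others[rng.integers(len(others))]
                clades[home].remove(tip)
                clades[target].append(tip)
    newick = "(" + ",".join(_clade_newick(tips) for tips in clades.values() if tips) + ");"
    tree = dendropy.Tree.get(data=newick, schema="newick", rooting="default-rooted",
                             preserve_underscores=True)
    return TaxonTree(tree=tree, assignments=assignments)


def summaries_from_specs(raw: pd.DataFrame):
    """Convenience: derive ContinuousSummary records from generated raw
    measurements (delegates to :func:`intdelim.io.summaries_from_raw`)."""
    from .io import summaries_from_raw

    return summaries_from_raw(raw)
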