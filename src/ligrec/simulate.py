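"""Synthetic paired population/stroma profiles with planted interactions.

The generator emulates the upstream study design end to end: two cell
populations measured on the same platform, a curated pair database, and a
known ground truth.  Gene intensities are log-normal (linear scale =
2**(log2-mean + noise)); each *planted* pair boosts its population-side
partner in the population (leaving it at baseline in the stroma, so the
differential-expression gate fires) and its stroma-side partner in the
stroma.  *Decoy* pairs are made unmatchable by construction: one partner is
forced below the presence threshold in both profiles, so ground truth is
exact rather than statistical.  Detection calls follow the threshold rule,
optionally corrupted at a configurable flip rate.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .database import PairDatabase, PairRecord, write_pair_table
from .degating import differential_genes
from .errors import ValidationError
from .expression import GeneExpression, PopulationProfile, write_profile_table
from .matching import match_interactions


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated experiment.

    Defaults mirror a typical small microarray design: log2 intensities
    centred at 7 (linear ≈ 128) with gene-to-gene spread 1, replicate noise
    0.5 on the log2 scale, a planted-partner boost of 5 log2 units (32-fold),
    a detection threshold of 50 linear units, and 3 replicate arrays.
    """

    n_genes: int = 200
    n_pairs: int = 40
    n_planted: int = 20
    n_replicates: int = 3
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.0
    effect_log2: float = 5.0
    noise_log2_sd: float = 0.5
    presence_threshold: float = 50.0
    call_flip_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 10:
            raise ValidationError("n_genes must be >= 10")
        if self.n_pairs < 1:
            raise ValidationError("n_pairs must be >= 1")
        if self.n_planted > self.n_pairs:
            raise ValidationError("n_planted must be <= n_pairs")
        if 2 * self.n_pairs > self.n_genes:
            raise ValidationError(
                f"{self.n_pairs} pairs need {2 * self.n_pairs} distinct genes "
                f"but only {self.n_genes} are simulated"
            )
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        for name in ("baseline_log2_sd", "noise_log2_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 <= self.call_flip_rate < 1:
            raise ValidationError("call_flip_rate must be in [0, 1)")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth: planted (pop_gene, stroma_gene, direction) triples and
    the decoy remainder of the database."""

    planted_pairs: tuple[tuple[str, str, str], ...]
    decoy_pairs: tuple[tuple[str, str], ...]

    @property
    def planted_keys(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b, _ in self.planted_pairs}


@dataclass
class SimulationResult:
    pop: PopulationProfile
    stroma: PopulationProfile
    db: PairDatabase
    truth: SimulationTruth
    config: SimulationConfig


def _profile(
    name: str,
    keys: list[str],
    symbols: list[str],
    log2_means: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> PopulationProfile:
    n, k = len(keys), config.n_replicates
    noise = rng.normal(0.0, config.noise_log2_sd, size=(n, k))
    intensities = 2.0 ** (log2_means[:, None] + noise)
    calls_present = intensities >= config.presence_threshold
    if config.call_flip_rate > 0:
        flips = rng.random(size=(n, k)) < config.call_flip_rate
        calls_present = calls_present ^ flips
    genes = {}
    for i, key in enumerate(keys):
        reps = tuple(float(v) for v in intensities[i])
        genes[key] = GeneExpression(
            key=key,
            symbol=symbols[i],
            mean_intensity=float(np.mean(reps)),
            replicate_intensities=reps,
            present=bool(calls_present[i].any()),
        )
    return PopulationProfile(name=name, genes=genes)


def simulate(config: SimulationConfig) -> SimulationResult:
    """Draw one synthetic experiment, fully reproducible from ``config.seed``.

    Returns the population profile, the stromal profile, the pair database
    (planted pairs first, then decoys, in a shuffled gene universe), and the
    exact ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    keys = [str(100001 + i) for i in range(config.n_genes)]
    symbols = [f"Gene{i:04d}" for i in range(config.n_genes)]
    mu = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)

    chosen = rng.choice(config.n_genes, size=2 * config.n_pairs, replace=False)
    pop_partners = chosen[0::2]
    stroma_partners = chosen[1::2]

    pop_shift = np.zeros(config.n_genes)
    stroma_shift = np.zeros(config.n_genes)
    forced_low = np.zeros(config.n_genes, dtype=bool)
    # margin of 4 log2 units below the threshold keeps decoys absent even at
    # several noise standard deviations
    low_mu = np.log2(max(config.presence_threshold, 2.0)) - 4.0

    planted, decoys = [], []
    for j in range(config.n_pairs):
        gp, gs = int(pop_partners[j]), int(stroma_partners[j])
        if j < config.n_planted:
            pop_shift[gp] += config.effect_log2
            stroma_shift[gs] += config.effect_log2
            planted.append((keys[gp], keys[gs], "pop_receptor__stroma_ligand"))
        else:
            forced_low[gs] = True
            decoys.append((keys[gp], keys[gs]))

    pop_mu = mu + pop_shift
    stroma_mu = mu + stroma_shift
    pop_mu[forced_low] = low_mu
    stroma_mu[forced_low] = low_mu

    pop = _profile("sim_pop", keys, symbols, pop_mu, config, rng)
    stroma = _profile("sim_stroma", keys, symbols, stroma_mu, config, rng)

    records = []
    for j in range(config.n_pairs):
        gp, gs = int(pop_partners[j]), int(stroma_partners[j])
        records.append(
            PairRecord(
                pair_id=f"sim{j:04d}",
                gene_a=keys[gp],
                gene_b=keys[gs],
                symbol_a=symbols[gp],
                symbol_b=symbols[gs],
                role_a="receptor",
                role_b="ligand",
                source="simulated",
            )
        )
    db = PairDatabase(records)
    truth = SimulationTruth(
        planted_pairs=tuple(planted), decoy_pairs=tuple(decoys)
    )
    return SimulationResult(pop=pop, stroma=stroma, db=db, truth=truth, config=config)


def recover_planted_pairs(
    sim: SimulationResult, alpha: float = 0.01, test: str = "welch_t"
) -> tuple[float, float]:
    """Run the full gate → match pipeline and score it against the truth.

    Returns (recall, false-discovery proportion) over unordered gene pairs.
    With a single replicate the gate is skipped (presence-only matching).
    """
    gate = None
    if sim.config.n_replicates >= 2:
        gate = differential_genes(sim.pop, sim.stroma, alpha=alpha, test=test)
    table = match_interactions(gate, sim.pop, sim.stroma, sim.db)
    found = table.pair_keys
    planted = sim.truth.planted_keys
    recall = len(found & planted) / max(len(planted), 1)
    fdp = len(found - planted) / max(len(found), 1)
    return recall, fdp


def write_simulation(sim: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Write population/stroma expression TSVs, the pair table, and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "population": outdir / "population.tsv",
        "stroma": outdir / "stroma.tsv",
        "pairs": outdir / "pairs.tsv",
        "truth": outdir / "truth.json",
    }
    write_profile_table(sim.pop, paths["population"])
    write_profile_table(sim.stroma, paths["stroma"])
    write_pair_table(sim.db, paths["pairs"])
    paths["truth"].write_text(
        json.dumps(
            {
                "config": asdict(sim.config),
                "planted_pairs": [list(t) for t in sim.truth.planted_pairs],
                "decoy_pairs": [list(t) for t in sim.truth.decoy_pairs],
            },
            indent=2,
        )
        + "\n",
        encoding="utf-8",
    )
    return paths
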