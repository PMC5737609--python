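"""Seeded generators for motifs, sequences, activities, and barcode counts.

The generators emulate the statistical structure the predictor assumes: a
construct library whose activity is a cluster-dependent sum of hinge terms of
TFBS enrichment scores (plus optional condition offsets and Gaussian noise),
observed through Poisson-sampled mRNA/DNA barcode counts.  The default
scenario plants twelve synthetic motifs into 5000 constructs of 250 bp: one
motif's copy number defines two clusters (a low-copy and a high-copy
population with different response functions), four motifs carry hinge
effects, and the rest are inactive decoys.  Every generator is a pure
function of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mars import BasisTerm, HingeFunction
from .motifs import PWMatrix, enrichment_matrix, reverse_complement

BASES = "ACGT"


@dataclass(frozen=True)
class ClusterResponse:
    offset: float
    terms: tuple[BasisTerm, ...]

    def evaluate(self, X: pd.DataFrame) -> np.ndarray:
        out = np.full(len(X), self.offset)
        for t in self.terms:
            out += t.coefficient * t.evaluate(X)
        return out


def _motif_id(i: int) -> str:
    return f"SYN{i:02d}"


def _default_responses() -> tuple[ClusterResponse, ClusterResponse]:
    h = HingeFunction
    low = ClusterResponse(
        offset=-2.0,
        terms=(
            BasisTerm((h(_motif_id(1), 1.5, +1),), 1.0),
            BasisTerm((h(_motif_id(2), 2.5, -1),), -0.8),
        ),
    )
    high = ClusterResponse(
        offset=2.0,
        terms=(
            BasisTerm((h(_motif_id(3), 1.5, +1),), 1.2),
            BasisTerm((h(_motif_id(1), 1.5, +1), h(_motif_id(4), 1.5, +1)), 0.3),
        ),
    )
    return low, high


@dataclass
class ScenarioSpec:
    """Full description of one simulated study; defaults are the reference
    scenario used by the recovery benchmarks."""

    n_motifs: int = 12
    motif_length: int = 10
    dominance: float = 0.9  # weight of the consensus base at each position
    scan_cutoff: float = 0.95  # planted sites are exact consensus (score 1.0)

    n_sequences: int = 5000
    sequence_length: int = 250
    cluster_motif: int = 0  # index of the cluster-defining motif
    cluster_threshold: float = 2.0
    cluster_prob: float = 0.5  # probability of the high-copy cluster
    low_copy_range: tuple[int, int] = (0, 1)  # inclusive
    high_copy_range: tuple[int, int] = (3, 4)
    n_effect_motifs: int = 4  # motifs 1..n carry hinge effects, 0..4 copies
    effect_copy_max: int = 4
    decoy_copy_n: int = 2  # decoy copies ~ Binomial(n, p)
    decoy_copy_p: float = 0.15
    site_mutation_rate: float = 0.0  # per-base mutation of planted sites

    responses: tuple[ClusterResponse, ClusterResponse] = field(
        default_factory=_default_responses
    )
    noise_sd: float = 0.3
    n_conditions: int = 1
    condition_offsets: tuple[float, ...] | None = None  # defaults to 0,1,2,...

    n_barcodes: int = 8
    n_replicates: int = 3
    depth: float = 500.0
    irregular_frac: float = 0.05
    irregular_sd: float = 1.5

    seed: int = 0

    def condition_labels(self) -> list[str]:
        if self.n_conditions <= 1:
            return ["none"]
        return [f"C{i}" for i in range(self.n_conditions)]

    def resolved_condition_offsets(self) -> np.ndarray:
        if self.condition_offsets is not None:
            offs = np.asarray(self.condition_offsets, dtype=float)
            if offs.shape != (self.n_conditions,):
                raise ValueError("condition_offsets must have one entry per condition")
            return offs
        return np.arange(self.n_conditions, dtype=float)


def _rng(spec: ScenarioSpec, stage: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stage])


def make_motifs(spec: ScenarioSpec) -> list[PWMatrix]:
    """Random informative PWMs with one dominant base per position."""
    rng = _rng(spec, 1)
    motifs = []
    other = (1.0 - spec.dominance) / 3.0
    for i in range(spec.n_motifs):
        consensus = rng.integers(0, 4, size=spec.motif_length)
        freqs = np.full((spec.motif_length, 4), other)
        freqs[np.arange(spec.motif_length), consensus] = spec.dominance
        motifs.append(PWMatrix(_motif_id(i), freqs, cutoff=spec.scan_cutoff))
    return motifs


def _sample_copies(spec: ScenarioSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Copy-number matrix (n_sequences x n_motifs) and the cluster flags."""
    n, m = spec.n_sequences, spec.n_motifs
    copies = np.zeros((n, m), dtype=int)
    is_high = rng.random(n) < spec.cluster_prob
    lo, hi = spec.low_copy_range, spec.high_copy_range
    copies[:, spec.cluster_motif] = np.where(
        is_high,
        rng.integers(hi[0], hi[1] + 1, size=n),
        rng.integers(lo[0], lo[1] + 1, size=n),
    )
    effect = [i for i in range(m) if i != spec.cluster_motif][: spec.n_effect_motifs]
    for j in effect:
        copies[:, j] = rng.integers(0, spec.effect_copy_max + 1, size=n)
    decoys = [i for i in range(m) if i != spec.cluster_motif and i not in effect]
    for j in decoys:
        copies[:, j] = rng.binomial(spec.decoy_copy_n, spec.decoy_copy_p, size=n)

    # keep total planted length within the sequence, trimming decoys first,
    # then effect copies; the cluster-defining copies are never trimmed
    cap = spec.sequence_length // spec.motif_length - 1
    trim_order = decoys[::-1] + effect[::-1]
    for row in range(n):
        excess = copies[row].sum() - cap
        for j in trim_order:
            if excess <= 0:
                break
            take = min(copies[row, j], excess)
            copies[row, j] -= take
            excess -= take
        if copies[row].sum() > cap:
            raise ValueError("infeasible packing: planted sites exceed sequence length")
    return copies, is_high


def make_sequences(
    spec: ScenarioSpec, motifs: list[PWMatrix]
) -> tuple[dict[str, str], pd.DataFrame]:
    """Uniform-background sequences with non-overlapping planted consensus
    occurrences (random strand, random gaps); the ledger records the planted
    copy number per (sequence, motif)."""
    if len(motifs) != spec.n_motifs:
        raise ValueError("motif list does not match the scenario")
    rng = _rng(spec, 2)
    copies, _ = _sample_copies(spec, rng)
    consensi = [m.consensus for m in motifs]
    sequences: dict[str, str] = {}
    L = spec.sequence_length
    ml = spec.motif_length
    base_arr = np.array(list(BASES))
    for row in range(spec.n_sequences):
        sid = f"seq{row:05d}"
        sites: list[str] = []
        for j in range(spec.n_motifs):
            for _ in range(copies[row, j]):
                site = consensi[j]
                if spec.site_mutation_rate > 0:
                    site = "".join(
                        BASES[rng.integers(0, 4)] if rng.random() < spec.site_mutation_rate else b
                        for b in site
                    )
                if rng.random() < 0.5:
                    site = reverse_complement(site)
                sites.append(site)
        order = rng.permutation(len(sites))
        background = base_arr[rng.integers(0, 4, size=L)]
        free = L - len(sites) * ml
        if free < 0:
            raise ValueError("infeasible packing: planted sites exceed sequence length")
        gaps = rng.multinomial(free, np.full(len(sites) + 1, 1.0 / (len(sites) + 1)))
        pos = 0
        seq = background.copy()
        for g, idx in zip(gaps[:-1], order):
            pos += int(g)
            seq[pos : pos + ml] = list(sites[idx])
            pos += ml
        sequences[sid] = "".join(seq)
    ledger = pd.DataFrame(
        copies,
        index=pd.Index(list(sequences), name="sequence_id"),
        columns=[_motif_id(i) for i in range(spec.n_motifs)],
    )
    return sequences, ledger


def make_activities(
    spec: ScenarioSpec, enrichments: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Cluster-dependent hinge response + condition offsets + Gaussian noise.

    Returns the activity table (one row per construct and condition) and a
    truth record holding every knot, coefficient, and noiseless value.
    """
    rng = _rng(spec, 3)
    cluster_col = _motif_id(spec.cluster_motif)
    is_high = enrichments[cluster_col].to_numpy(dtype=float) >= spec.cluster_threshold
    low, high = spec.responses
    y_true = np.where(is_high, high.evaluate(enrichments), low.evaluate(enrichments))
    labels = spec.condition_labels()
    offsets = spec.resolved_condition_offsets() if spec.n_conditions > 1 else np.zeros(1)
    rows = []
    truth_values = {}
    for ci, label in enumerate(labels):
        noiseless = y_true + offsets[ci]
        noisy = noiseless + rng.normal(0.0, spec.noise_sd, size=len(noiseless))
        truth_values[label] = pd.Series(noiseless, index=enrichments.index)
        for sid, value in zip(enrichments.index, noisy):
            rows.append({"construct_id": sid, "condition": label, "activity": float(value)})
    activities = pd.DataFrame(rows)
    truth = {
        "cluster_column": cluster_col,
        "cluster_threshold": spec.cluster_threshold,
        "responses": {
            "low": spec.responses[0],
            "high": spec.responses[1],
        },
        "condition_offsets": dict(zip(labels, offsets)),
        "noiseless": truth_values,
        "is_high": pd.Series(is_high, index=enrichments.index),
    }
    return activities, truth


def make_counts(activities: pd.DataFrame, spec: ScenarioSpec) -> tuple[pd.DataFrame, list[str]]:
    """Poisson barcode counts consistent with the given activities.

    dna ~ Poisson(depth); mrna ~ Poisson(depth * 2**activity), per barcode and
    replicate.  A seeded fraction of constructs receives extra per-replicate
    activity noise (the "irregular" set, returned for ground-truth checks).
    """
    if spec.depth <= 0:
        raise ValueError("depth must be positive")
    rng = _rng(spec, 4)
    constructs = activities["construct_id"].unique()
    n_irr = int(round(spec.irregular_frac * len(constructs)))
    irregular = set(rng.choice(constructs, size=n_irr, replace=False)) if n_irr else set()

    n_rows = len(activities)
    R, B = spec.n_replicates, spec.n_barcodes
    act = activities["activity"].to_numpy(dtype=float)
    rep_act = np.repeat(act[:, None], R, axis=1)
    irr_mask = activities["construct_id"].isin(irregular).to_numpy()
    if irr_mask.any():
        rep_act[irr_mask] += rng.normal(0.0, spec.irregular_sd, size=(int(irr_mask.sum()), R))
    lam = spec.depth * np.power(2.0, np.clip(rep_act, -20, 20))  # (n_rows, R)
    dna = rng.poisson(spec.depth, size=(n_rows, R, B))
    mrna = rng.poisson(np.broadcast_to(lam[:, :, None], (n_rows, R, B)))
    counts = pd.DataFrame({
        "construct_id": np.repeat(activities["construct_id"].to_numpy(), R * B),
        "barcode": np.tile([f"bc{b}" for b in range(B)], n_rows * R),
        "replicate": np.tile(np.repeat(np.arange(R), B), n_rows),
        "dna_count": dna.ravel(),
        "mrna_count": mrna.ravel(),
        "condition": np.repeat(activities["condition"].to_numpy(), R * B),
    })
    return counts, sorted(irregular)


@dataclass
class SimulatedDataset:
    spec: ScenarioSpec
    motifs: list[PWMatrix]
    sequences: dict[str, str]
    ledger: pd.DataFrame
    enrichments: pd.DataFrame
    activities: pd.DataFrame
    truth: dict


def simulate_dataset(spec: ScenarioSpec | None = None, with_counts: bool = False):
    """Run the whole generator chain for one scenario.

    Returns a SimulatedDataset; with ``with_counts`` the tuple
    (dataset, counts, irregular_ids) instead.
    """
    spec = spec or ScenarioSpec()
    motifs = make_motifs(spec)
    sequences, ledger = make_sequences(spec, motifs)
    enrichments = enrichment_matrix(motifs, sequences)
    activities, truth = make_activities(spec, enrichments)
    ds = SimulatedDataset(spec, motifs, sequences, ledger, enrichments, activities, truth)
    if with_counts:
        counts, irregular = make_counts(activities, spec)
        return ds, counts, irregular
    return ds
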