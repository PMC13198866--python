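"""Seeded synthetic sequence pairs along a divergence gradient.

An ancestor sequence is drawn uniformly over the 20 canonical amino
acids and a derived copy is produced under a simple site-wise mutation
model: substitutions replace a residue with one of the other 19,
insertions and deletions occur per site with geometric lengths.  The
model is deliberately minimal — it emulates a divergence axis, not any
particular evolutionary process — and is fully seeded so every test
input is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_dag import AlignmentParams, build_suboptimal_dag
from .io_formats import SequenceRecord
from .matrices import CANONICAL_AA
from .safety import compute_safety, count_paths

__all__ = ["DivergenceModel", "generate_pair", "divergence_experiment"]

MAX_LENGTH = 200
MAX_REPLICATES = 50


@dataclass
class DivergenceModel:
    """Parameters of the mutation model producing one sequence pair."""

    length: int = 100
    substitution_rate: float = 0.1
    indel_rate: float = 0.02
    indel_mean: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be positive")
        for attr in ("substitution_rate", "indel_rate"):
            v = getattr(self, attr)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{attr} must be in [0, 1], got {v}")
        if self.indel_mean < 1.0:
            raise ValueError("indel_mean must be >= 1")


def generate_pair(model: DivergenceModel) -> tuple[SequenceRecord, SequenceRecord]:
    """Draw an (ancestor, derived) pair; identical seeds give identical
    pairs."""
    rng = np.random.default_rng(model.seed)
    aa = list(CANONICAL_AA)
    ancestor = "".join(rng.choice(aa, size=model.length))
    p_indel = model.indel_rate / 2.0  # split evenly between ins and del
    derived: list[str] = []
    i = 0
    while i < model.length:
        if p_indel and rng.random() < p_indel:
            # insertion before this site
            g = int(rng.geometric(1.0 / model.indel_mean))
            derived.extend(rng.choice(aa, size=g))
        if p_indel and rng.random() < p_indel:
            # deletion of a run starting at this site
            g = int(rng.geometric(1.0 / model.indel_mean))
            i += g
            continue
        ch = ancestor[i]
        if model.substitution_rate and rng.random() < model.substitution_rate:
            others = [a for a in aa if a != ch]
            ch = others[int(rng.integers(len(others)))]
        derived.append(ch)
        i += 1
    if not derived:
        derived.append(aa[int(rng.integers(len(aa)))])
    desc_a = (
        f"ancestor synthetic length={model.length} seed={model.seed}"
    )
    desc_b = (
        f"derived synthetic sub={model.substitution_rate} "
        f"indel={model.indel_rate} seed={model.seed}"
    )
    return (
        SequenceRecord("ancestor", desc_a, ancestor),
        SequenceRecord("derived", desc_b, "".join(derived)),
    )


def divergence_experiment(
    lengths: Sequence[int],
    divergences: Sequence[float],
    replicates: int,
    params: AlignmentParams,
    seed: int = 0,
    delta_scale: float = 0.2,
    indel_fraction: float = 0.2,
) -> pd.DataFrame:
    """Safe-coverage summary across a divergence gradient.

    For each (length, divergence) cell, ``replicates`` seeded pairs are
    generated with substitution rate equal to the divergence level and
    indel rate ``indel_fraction`` times it; Δ is scaled to the sequence
    length as ``max(1, round(delta_scale * length))``.  Reported per
    cell: mean safe coverage (averaged over both sequences), mean window
    count, mean window length and the mean number of decimal digits of
    the alignment count T.
    """
    if replicates < 1 or replicates > MAX_REPLICATES:
        raise ValueError(f"replicates must be in [1, {MAX_REPLICATES}]")
    for length in lengths:
        if length > MAX_LENGTH:
            raise ValueError(f"length {length} exceeds the bound {MAX_LENGTH}")
    rows = []
    for li, length in enumerate(lengths):
        delta = max(1, round(delta_scale * length))
        run_params = AlignmentParams(
            matrix=params.matrix,
            gap_open=params.gap_open,
            gap_extend=params.gap_extend,
            delta=delta,
            alpha=params.alpha,
        )
        for di, div in enumerate(divergences):
            covs, wins, wlens, tdigits = [], [], [], []
            for rep in range(replicates):
                pair_seed = int(
                    np.random.SeedSequence(
                        entropy=seed, spawn_key=(li, di, rep)
                    ).generate_state(1)[0]
                    % (2**31)
                )
                model = DivergenceModel(
                    length=length,
                    substitution_rate=div,
                    indel_rate=div * indel_fraction,
                    seed=pair_seed,
                )
                rec_a, rec_b = generate_pair(model)
                dag = build_suboptimal_dag(rec_a.residues, rec_b.residues, run_params)
                counts = count_paths(dag)
                result = compute_safety(dag, counts, with_edge_track=False)
                covs.append((result.safe_coverage_a + result.safe_coverage_b) / 2)
                wins.append(len(result.windows))
                wlens.append(
                    float(
                        np.mean(
                            [w.a_interval[1] - w.a_interval[0] for w in result.windows]
                        )
                    )
                    if result.windows
                    else 0.0
                )
                tdigits.append(len(str(counts.total)))
            rows.append(
                {
                    "length": length,
                    "divergence": div,
                    "delta": delta,
                    "alpha": float(run_params.alpha),
                    "n_replicates": replicates,
                    "mean_safe_coverage": float(np.mean(covs)),
                    "mean_window_count": float(np.mean(wins)),
                    "mean_window_length": float(np.mean(wlens)),
                    "mean_t_digits": float(np.mean(tdigits)),
                }
            )
    return pd.DataFrame(rows)
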