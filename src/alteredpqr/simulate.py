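"""Synthetic quantitative-proteomics datasets with known ground truth.

The generator emulates the statistical structure the pair-ratio screen
assumes: log2-scale protein abundances with per-protein baselines, shared
latent factors inducing co-regulation within complexes, i.i.d. technical
noise, missing values, and four kinds of injected events —

* ``shift_pair``: a pair-ratio shift (delta added to the alphabetically
  first protein, or split oppositely across both) in a random subset of
  test samples;
* ``corgain_pair``: a correlation gain (a shared latent factor added to
  both proteins only in the target group);
* ``hub``: one protein shifted in every test sample (the redundancy
  scenario);
* ``shift_complex``: every member of a complex shifted together in a
  subset of test samples.

Defaults mirror the screen's calibration assumptions: baselines ~
N(20, 2) log2 units and noise sd 0.25 so null ratios rarely exceed
|Mi| = 3.5; a 10-reference / 24-test layout (the cell-line setting);
mild within-complex co-regulation and 5% missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import make_pairs, pair_id, write_table


@dataclass
class SimulationConfig:
    """Stated world of one synthetic dataset. ``seed`` is mandatory."""

    seed: int
    n_proteins: int = 120
    n_ref: int = 10
    n_test: int = 24
    n_complexes: int = 20
    complex_size_range: tuple = (3, 6)
    baseline_mean: float = 20.0      # log2 units
    baseline_sd: float = 2.0         # log2 units
    noise_sd: float = 0.25           # log2 units
    coreg_sd: float = 0.15           # latent-factor weight, log2 units
    #: list of ((protein_a, protein_b), delta, fraction of test samples)
    shift_pairs: list = field(default_factory=list)
    #: list of ((protein_a, protein_b), latent weight, target group)
    corgain_pairs: list = field(default_factory=list)
    #: list of (protein, delta) shifted in every test sample
    hub_proteins: list = field(default_factory=list)
    #: list of (complex_id, delta, fraction of test samples)
    shift_complexes: list = field(default_factory=list)
    split_shift: bool = False        # split pair shifts oppositely (+/- d/2)
    missing_rate: float = 0.05

    def validate(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        lo, hi = self.complex_size_range
        if lo < 2 or hi < lo:
            raise ValueError("complex_size_range must be (lo >= 2, hi >= lo)")
        for _, _, frac in self.shift_pairs:
            if not 0 <= frac <= 1:
                raise ValueError("shift fraction must be in [0, 1]")
        for _, _, frac in self.shift_complexes:
            if not 0 <= frac <= 1:
                raise ValueError("shift fraction must be in [0, 1]")
        return self


def protein_name(i: int) -> str:
    return f"P{i:04d}"


def _sample_names(config):
    ref = [f"R{i + 1:02d}" for i in range(config.n_ref)]
    test = [f"T{i + 1:02d}" for i in range(config.n_test)]
    return ref, test


def simulate_dataset(config: SimulationConfig):
    """Generate one dataset.

    Returns ``(matrix, design, pairs, catalog, truth)``: the protein ×
    sample log2 matrix, sample design, pair table (all within-complex pairs
    plus injected pairs), complex catalog and the ground-truth event table.
    Fully deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    proteins = [protein_name(i) for i in range(config.n_proteins)]
    ref_names, test_names = _sample_names(config)
    samples = ref_names + test_names
    n_s = len(samples)

    # complex membership: disjoint blocks of proteins
    catalog_rows = []
    members = {}
    cursor = 0
    lo, hi = config.complex_size_range
    for c in range(config.n_complexes):
        size = int(rng.integers(lo, hi + 1))
        if cursor + size > config.n_proteins:
            break
        cid = f"CPX{c + 1:03d}"
        mem = proteins[cursor:cursor + size]
        members[cid] = mem
        for m in mem:
            catalog_rows.append((cid, f"complex_{c + 1:03d}", m))
        cursor += size
    catalog = pd.DataFrame(catalog_rows,
                           columns=["complex_id", "name", "member_id"])

    baseline = rng.normal(config.baseline_mean, config.baseline_sd,
                          config.n_proteins)
    values = np.tile(baseline[:, None], (1, n_s))
    # within-complex co-regulation via one latent factor per complex
    pidx = {p: k for k, p in enumerate(proteins)}
    for cid, mem in members.items():
        latent = rng.normal(0.0, 1.0, n_s)
        rows = [pidx[m] for m in mem]
        values[rows] += config.coreg_sd * latent[None, :]
    values += rng.normal(0.0, config.noise_sd, values.shape)

    truth_rows = []
    test_offset = config.n_ref

    for (a, b), delta, frac in config.shift_pairs:
        a, b = sorted((a, b))
        k = int(np.ceil(frac * config.n_test))
        chosen = rng.choice(config.n_test, size=k, replace=False)
        cols = test_offset + chosen
        if config.split_shift:
            values[pidx[a]][cols] += delta / 2.0
            values[pidx[b]][cols] -= delta / 2.0
        else:
            values[pidx[a]][cols] += delta
        truth_rows.append(("shift_pair", pair_id(a, b),
                           ";".join(test_names[c] for c in sorted(chosen)),
                           delta))

    for (a, b), weight, group in config.corgain_pairs:
        if group == "reference":
            cols = np.arange(config.n_ref)
            names = ref_names
        elif group == "test":
            cols = test_offset + np.arange(config.n_test)
            names = test_names
        else:
            raise ValueError(f"unknown corgain target group {group!r}")
        latent = rng.normal(0.0, 1.0, len(cols))
        values[pidx[a]][cols] += weight * latent
        values[pidx[b]][cols] += weight * latent
        truth_rows.append(("corgain_pair", pair_id(a, b),
                           ";".join(names), weight))

    for prot, delta in config.hub_proteins:
        values[pidx[prot]][test_offset:] += delta
        truth_rows.append(("hub", prot, ";".join(test_names), delta))

    for cid, delta, frac in config.shift_complexes:
        k = int(np.ceil(frac * config.n_test))
        chosen = rng.choice(config.n_test, size=k, replace=False)
        cols = test_offset + chosen
        for m in members[cid]:
            values[pidx[m]][cols] += delta
        truth_rows.append(("shift_complex", cid,
                           ";".join(test_names[c] for c in sorted(chosen)),
                           delta))

    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values = np.where(mask, np.nan, values)

    matrix = pd.DataFrame(values, index=pd.Index(proteins, name="protein_id"),
                          columns=samples)
    design = pd.DataFrame(
        {"group": ["reference"] * config.n_ref + ["test"] * config.n_test},
        index=pd.Index(samples, name="sample_id"))
    design["subtype"] = design["group"]

    tuples = set()
    for mem in members.values():
        for i in range(len(mem)):
            for j in range(i + 1, len(mem)):
                tuples.add(tuple(sorted((mem[i], mem[j]))))
    for (a, b), _, _ in config.shift_pairs:
        tuples.add(tuple(sorted((a, b))))
    for (a, b), _, _ in config.corgain_pairs:
        tuples.add(tuple(sorted((a, b))))
    pairs = make_pairs(sorted(tuples), matrix=matrix)

    truth = pd.DataFrame(truth_rows, columns=["event_type", "target",
                                              "affected_samples", "magnitude"])
    return matrix, design, pairs, catalog, truth


def ground_truth_table(truth: pd.DataFrame, path=None) -> pd.DataFrame:
    """Ground-truth events as a machine-joinable table (one row per event,
    ``target`` joins on pair/protein/complex IDs); optionally written to
    ``path`` as TSV (header-only when empty)."""
    table = truth.copy() if len(truth) else pd.DataFrame(
        columns=["event_type", "target", "affected_samples", "magnitude"])
    if path is not None:
        write_table(table, path, index=False)
    return table
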