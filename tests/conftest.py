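import numpy as np
import pandas as pd
import pytest

import spliceqtl as sq


@pytest.fixture(scope="session")
def gene():
    return sq.default_gene_model()


@pytest.fixture(scope="session")
def probe_key(gene):
    return sq.probe_junction_of(gene)


def make_covariates(n, n_copd=0, seed=0):
    return sq.simulate_cohort(n, n_copd, seed=seed)


@pytest.fixture()
def small_cohort():
    genotypes = sq.simulate_genotypes(60, [(3, 0.3, 0.95)], 2, seed=21)
    covariates = make_covariates(60, 25, seed=22)
    return genotypes, covariates


def reference_walk_junctions(pos, cigar):
    """Independent per-base reference-coordinate walk oracle.

    Advances the reference pointer one base at a time and records the first
    and last reference base of every N run. Deliberately character-by-
    character, sharing no code with the package implementation.
    """
    lengths = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            lengths.append((int(num), ch))
            num = ""
    ref = pos
    out = []
    for ln, op in lengths:
        if op == "N":
            first = None
            last = None
            for _ in range(ln):
                if first is None:
                    first = ref
                last = ref
                ref += 1
            out.append((first, last))
        elif op in "MD=X":
            for _ in range(ln):
                ref += 1
    return out


def random_cigar(rng):
    """Random structurally valid CIGAR over M/I/D/N/S/H/=/X."""
    parts = []
    if rng.random() < 0.15:
        parts.append(f"{rng.integers(1, 6)}H")
    if rng.random() < 0.25:
        parts.append(f"{rng.integers(1, 20)}S")
    n_core = rng.integers(1, 8)
    prev_gap = True
    for _ in range(n_core):
        op = rng.choice(["M", "=", "X"]) if prev_gap else rng.choice(
            ["M", "I", "D", "N", "=", "X"]
        )
        prev_gap = op in "IDN"
        parts.append(f"{rng.integers(1, 300)}{op}")
    if not parts[-1].endswith(("M", "=", "X")):
        parts.append(f"{rng.integers(1, 100)}M")
    if rng.random() < 0.25:
        parts.append(f"{rng.integers(1, 20)}S")
    if rng.random() < 0.15:
        parts.append(f"{rng.integers(1, 6)}H")
    return "".join(parts)
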