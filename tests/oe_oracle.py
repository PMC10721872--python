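"""Brute-force reference implementation of the OE score.

A deliberately plain, loop-based transliteration of the scoring recipe
(average expression with the bulk/scRNA branch, 50-style equal-frequency
bins, row centering, signature mean, bin-matched random null), kept
independent of the package implementation except for the documented RNG
contract (per-list generator keyed by the seed and the sorted gene list;
per-bin uniform draws without replacement in ascending bin order).
"""

from __future__ import annotations

import hashlib
import math

import numpy as np


def _oracle_list_rng(seed: int, genes) -> np.random.Generator:
    digest = hashlib.sha256("\x1f".join(sorted(genes)).encode()).digest()
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int.from_bytes(digest[:8], "big")])
    )


def oracle_oe(matrix, signature, n_random: int, seed: int, n_bins: int):
    """Per-sample signed OE scores computed from first principles."""
    genes = list(matrix.genes)
    C = np.asarray(matrix.values, dtype=float)
    n_genes, n_samples = C.shape

    # average expression, bulk vs scRNA branch
    E = []
    for i in range(n_genes):
        if matrix.modality == "bulk":
            E.append(math.fsum(C[i]) / n_samples)
        else:
            tpm_sum = math.fsum(10.0 * (2.0 ** C[i, j] - 1.0) for j in range(n_samples))
            E.append(math.log2(tpm_sum / n_samples + 1.0))
    E = np.array(E)

    # equal-frequency bins by rank, stable ties, earlier bins take extras
    order = np.argsort(E, kind="stable")
    bin_of = np.empty(n_genes, dtype=int)
    base, extra = divmod(n_genes, n_bins)
    pos = 0
    for b in range(1, n_bins + 1):
        size = base + (1 if b <= extra else 0)
        for i in order[pos : pos + size]:
            bin_of[i] = b
        pos += size

    # row-centered matrix
    Z = np.empty_like(C)
    for i in range(n_genes):
        mean_i = math.fsum(C[i]) / n_samples
        Z[i] = C[i] - mean_i

    lookup = {g: i for i, g in enumerate(genes)}

    def score(idx) -> np.ndarray:
        idx = sorted(idx)
        return np.array(
            [math.fsum(Z[i, j] for i in idx) / len(idx) for j in range(n_samples)]
        )

    def arm(gene_list) -> np.ndarray:
        idx = [lookup[g] for g in gene_list]
        s = score(idx)
        counts: dict[int, int] = {}
        for i in idx:
            counts[bin_of[i]] = counts.get(bin_of[i], 0) + 1
        rng = _oracle_list_rng(seed, gene_list)
        total = np.zeros(n_samples)
        for _ in range(n_random):
            drawn: list[int] = []
            for b in range(1, n_bins + 1):
                c = counts.get(b, 0)
                if c == 0:
                    continue
                members = np.array([i for i in range(n_genes) if bin_of[i] == b])
                drawn.extend(rng.choice(members, size=c, replace=False).tolist())
            total += score(drawn)
        return s - total / n_random

    oe = arm(signature.up)
    if signature.down:
        oe = oe - arm(signature.down)
    return oe
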