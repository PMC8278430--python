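import itertools
import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

# QC exclusions are intentionally chatty at WARNING; keep test output readable
logging.getLogger("mirpanel").setLevel(logging.ERROR)


def brute_force_u(case, control):
    """Independent pairwise count of the Mann-Whitney U (case over control)."""
    u = 0.0
    for x in case:
        for y in control:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def enumerate_exact_p(case, control):
    """Two-sided exact Mann-Whitney p by full enumeration of group labelings.

    Walks every way of assigning the pooled values to a 'case' set of the
    observed size, builds the exact U null, and doubles the smaller tail
    (capping at 1) — independent of any library routine.
    """
    pooled = list(case) + list(control)
    n1 = len(case)
    u_obs = brute_force_u(case, control)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        c = [pooled[i] for i in idx]
        k = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(brute_force_u(c, k))
    us = np.asarray(us)
    n_total = len(us)
    p_ge = np.sum(us >= u_obs - 1e-9) / n_total
    p_le = np.sum(us <= u_obs + 1e-9) / n_total
    return min(1.0, 2.0 * min(p_ge, p_le))


def brute_force_pathway_counts(targets, gene_sets):
    """Double-loop oracle for overlap and pathway-hit counts.

    ``targets``: dict mirna -> iterable of genes; ``gene_sets``: dict
    set_id -> iterable of genes.  Returns (unique, multi, hits_per_set,
    genes_in_pathways, pathways_hit).
    """
    seen = {}
    for genes in targets.values():
        for g in set(genes):
            seen[g] = seen.get(g, 0) + 1
    unique = len(seen)
    multi = sum(1 for v in seen.values() if v >= 2)
    union = set(seen)
    hits = {}
    genes_in = set()
    for sid, genes in gene_sets.items():
        h = set()
        for g in genes:
            if g in union:
                h.add(g)
        if h:
            hits[sid] = len(h)
            genes_in |= h
    return unique, multi, hits, len(genes_in), len(hits)


@pytest.fixture
def expr_two_markers():
    """Tiny dCt table: one clean marker contrast, both polarities."""
    rows = []
    for i, v in enumerate([3.5, 4.0, 4.1]):
        rows.append((f"case_{i}", "case", "up_marker", v))
        rows.append((f"case_{i}", "case", "down_marker", 7.0 + v))
    for i, v in enumerate([6.0, 6.2]):
        rows.append((f"ctrl_{i}", "control", "up_marker", v))
        rows.append((f"ctrl_{i}", "control", "down_marker", v - 1.0))
    return pd.DataFrame(rows, columns=["sample_id", "group", "marker", "delta_ct"])
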