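"""Numba kernels for the structured-coalescent engine.

These are internal: `coalescent` wraps them behind typed APIs. Trees are
encoded as (parents, times) arrays with leaves 0..n-1 at time 0 and internal
nodes numbered in coalescence order, so a parent's index always exceeds its
children's — downstream accumulation can run a single forward pass.
"""

import numpy as np
from numba import njit

__all__ = ["simulate_trees", "accumulate_branch_sfs", "simulate_sites"]


@njit(cache=True)
def simulate_trees(n_sims, sample_demes, epoch_ends, sizes, mig, dest, seed):
    """Simulate coalescent trees under a piecewise-constant structured model.

    sample_demes : int64[n]        initial deme of each haploid sample
    epoch_ends   : float64[E]      end time (generations) of each epoch; last = inf
    sizes        : float64[E, D]   diploid deme sizes per epoch
    mig          : float64[E, D, D] backward per-lineage migration rates, diag 0
    dest         : int64[E, D]     deme remapping applied on *entering* epoch e
    Returns (parents int64[n_sims, 2n-1], times float64[n_sims, 2n-1]);
    the root (index 2n-2) has parent -1.
    """
    np.random.seed(seed)
    n = sample_demes.shape[0]
    n_demes = sizes.shape[1]
    n_nodes = 2 * n - 1
    parents = np.full((n_sims, n_nodes), -1, np.int64)
    times = np.zeros((n_sims, n_nodes))

    act_node = np.empty(n, np.int64)
    act_deme = np.empty(n, np.int64)
    kd = np.empty(n_demes, np.int64)
    coal = np.empty(n_demes)
    out_rate = np.empty(n_demes)

    for s in range(n_sims):
        for i in range(n):
            act_node[i] = i
            act_deme[i] = sample_demes[i]
        k = n
        next_node = n
        t = 0.0
        e = 0
        while k > 1:
            for d in range(n_demes):
                kd[d] = 0
            for i in range(k):
                kd[act_deme[i]] += 1
            total = 0.0
            for d in range(n_demes):
                coal[d] = kd[d] * (kd[d] - 1) / (4.0 * sizes[e, d])
                o = 0.0
                for b in range(n_demes):
                    o += mig[e, d, b]
                out_rate[d] = o
                total += coal[d] + kd[d] * o
            if total <= 0.0:
                # nothing can happen in this epoch; advance to the boundary
                t = epoch_ends[e]
                e += 1
                for i in range(k):
                    act_deme[i] = dest[e, act_deme[i]]
                continue
            dt = np.random.exponential(1.0 / total)
            if t + dt >= epoch_ends[e]:
                t = epoch_ends[e]
                e += 1
                for i in range(k):
                    act_deme[i] = dest[e, act_deme[i]]
                continue
            t += dt
            u = np.random.random() * total
            chosen = -1
            is_coal = False
            for d in range(n_demes):
                if u < coal[d]:
                    chosen = d
                    is_coal = True
                    break
                u -= coal[d]
                r = kd[d] * out_rate[d]
                if u < r:
                    chosen = d
                    break
                u -= r
            if chosen < 0:  # numerical guard: attribute to last nonempty deme
                for d in range(n_demes - 1, -1, -1):
                    if kd[d] > 1:
                        chosen = d
                        is_coal = True
                        break
                if chosen < 0:
                    continue
            if is_coal:
                r1 = np.random.randint(kd[chosen])
                r2 = np.random.randint(kd[chosen] - 1)
                if r2 >= r1:
                    r2 += 1
                i1 = -1
                i2 = -1
                c = 0
                for i in range(k):
                    if act_deme[i] == chosen:
                        if c == r1:
                            i1 = i
                        if c == r2:
                            i2 = i
                        c += 1
                nn = next_node
                next_node += 1
                parents[s, act_node[i1]] = nn
                parents[s, act_node[i2]] = nn
                times[s, nn] = t
                act_node[i1] = nn
                act_node[i2] = act_node[k - 1]
                act_deme[i2] = act_deme[k - 1]
                k -= 1
            else:
                r1 = np.random.randint(kd[chosen])
                i1 = -1
                c = 0
                for i in range(k):
                    if act_deme[i] == chosen:
                        if c == r1:
                            i1 = i
                            break
                        c += 1
                v = np.random.random() * out_rate[chosen]
                b = n_demes - 1
                for d in range(n_demes):
                    if v < mig[e, chosen, d]:
                        b = d
                        break
                    v -= mig[e, chosen, d]
                act_deme[i1] = b
    return parents, times


@njit(cache=True)
def accumulate_branch_sfs(parents, times, leaf_pop, n0, n1, n2):
    """Accumulate branch length into joint allele-count configurations.

    Each non-root branch subtends a set of samples; its length adds mass to
    the (c0, c1, c2) cell counting subtended samples per population group.
    Returns the *unfolded* accumulation; folding is a cheap array op outside.
    """
    n_sims, n_nodes = parents.shape
    n = (n_nodes + 1) // 2
    acc = np.zeros((n0 + 1, n1 + 1, n2 + 1))
    cfg = np.zeros((n_nodes, 3), np.int64)
    for s in range(n_sims):
        for v in range(n_nodes):
            cfg[v, 0] = 0
            cfg[v, 1] = 0
            cfg[v, 2] = 0
        for i in range(n):
            cfg[i, leaf_pop[i]] = 1
        for v in range(n_nodes - 1):
            p = parents[s, v]
            bl = times[s, p] - times[s, v]
            acc[cfg[v, 0], cfg[v, 1], cfg[v, 2]] += bl
            cfg[p, 0] += cfg[v, 0]
            cfg[p, 1] += cfg[v, 1]
            cfg[p, 2] += cfg[v, 2]
    return acc


@njit(cache=True)
def simulate_sites(parents, times, rate_per_tree_length, seed):
    """Drop infinite-sites mutations on a batch of trees.

    Mutation count per tree ~ Poisson(rate * total branch length); each
    mutation lands on a branch with probability proportional to its length
    and marks all subtended leaves as carrying the derived allele.
    Returns (derived uint8[n_sites, n_leaves], site_tree int64[n_sites]).
    """
    np.random.seed(seed)
    n_sims, n_nodes = parents.shape
    n = (n_nodes + 1) // 2
    tree_len = np.empty(n_sims)
    n_mut = np.empty(n_sims, np.int64)
    for s in range(n_sims):
        L = 0.0
        for v in range(n_nodes - 1):
            L += times[s, parents[s, v]] - times[s, v]
        tree_len[s] = L
        n_mut[s] = np.random.poisson(rate_per_tree_length * L)
    total = 0
    for s in range(n_sims):
        total += n_mut[s]
    derived = np.zeros((total, n), np.uint8)
    site_tree = np.empty(total, np.int64)
    child1 = np.full(n_nodes, -1, np.int64)
    child2 = np.full(n_nodes, -1, np.int64)
    cum = np.empty(n_nodes - 1)
    stack = np.empty(n_nodes, np.int64)
    idx = 0
    for s in range(n_sims):
        if n_mut[s] == 0:
            continue
        for v in range(n_nodes):
            child1[v] = -1
            child2[v] = -1
        for v in range(n_nodes - 1):
            p = parents[s, v]
            if child1[p] < 0:
                child1[p] = v
            else:
                child2[p] = v
        c = 0.0
        for v in range(n_nodes - 1):
            c += times[s, parents[s, v]] - times[s, v]
            cum[v] = c
        for _ in range(n_mut[s]):
            u = np.random.random() * tree_len[s]
            node = np.searchsorted(cum, u)
            if node >= n_nodes - 1:
                node = n_nodes - 2
            top = 0
            stack[top] = node
            top += 1
            while top > 0:
                top -= 1
                v = stack[top]
                if v < n:
                    derived[idx, v] = 1
                else:
                    stack[top] = child1[v]
                    top += 1
                    stack[top] = child2[v]
                    top += 1
            site_tree[idx] = s
            idx += 1
    return derived, site_tree
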