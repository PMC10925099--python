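"""Numba kernels for the individual-based Wright-Fisher forward simulator.

Haplotypes are stored CSR-style as parallel arrays indexed by ``indptr``
(length 2N+1): mutation id (int32, into small global attribute tables),
genomic position (float32, continuous gene coordinate), the heterozygous
log-fitness contribution ln(1-sh) (float32) and a class flag.  Log fitness
is the sum of ln(1-sh) over both haplotypes plus a homozygosity correction
ln(1-s) - 2 ln(1-sh) at sites carried on both.  The correction is only
applied at "selected" sites, flagged at birth when |ln(1-s) - 2 ln(1-sh)|
exceeds 1e-5; for the remaining quasi-neutral sites (additive, or s below
~6e-3) the correction is O(s^2) and dropping it changes log fitness by under
1e-3 per genome.  Selected sites are mirrored in a tiny per-haplotype
sidecar, so per-individual fitness is two vectorized sums plus a merge of
~10-element runs instead of a branchy merge over every site.

All randomness flows through numba's np.random state, seeded once per
replicate, so runs are bit-reproducible for a given seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_GROW_IDS = 1
STATUS_GROW_MUTS = 2
STATUS_GROW_SEL = 3

#: |ln(1-s) - 2 ln(1-sh)| above which a site gets exact homozygote handling
SEL_CORR_TOL = 1e-5


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, fastmath=True)
def fitness(indptr, lws, sel_indptr, sel_ids, sel_poss, sel_lws, lw_hom, n_ind, w_out):
    """Multiplicative fitness per diploid (see module docstring)."""
    for i in range(n_ind):
        acc = 0.0
        for t in range(indptr[2 * i], indptr[2 * i + 2]):
            acc += lws[t]
        a = sel_indptr[2 * i]
        a1 = sel_indptr[2 * i + 1]
        b = a1
        b1 = sel_indptr[2 * i + 2]
        while a < a1 and b < b1:
            pa = sel_poss[a]
            pb = sel_poss[b]
            if pa < pb:
                a += 1
            elif pb < pa:
                b += 1
            elif sel_ids[a] == sel_ids[b]:
                acc += lw_hom[sel_ids[a]] - sel_lws[a] - sel_lws[b]
                a += 1
                b += 1
            else:
                a += 1
        w_out[i] = np.exp(acc)


@njit(cache=True)
def choose_parents(w, n_par, n_off, out):
    """Fitness-proportional parent index per gamete (2 per offspring)."""
    cw = np.empty(n_par)
    tot = 0.0
    for i in range(n_par):
        tot += w[i]
        cw[i] = tot
    for k in range(2 * n_off):
        u = np.random.random() * tot
        lo = 0
        hi = n_par - 1
        while lo < hi:
            mid = (lo + hi) // 2
            if cw[mid] < u:
                lo = mid + 1
            else:
                hi = mid
        out[k] = lo


@njit(cache=True, inline="always")
def _gallop(poss, lo, hi, target):
    """First index in [lo, hi) with poss >= target (sorted run)."""
    step = 1
    j = lo
    while j < hi and poss[j] < target:
        j += step
        step <<= 1
    upper = j if j < hi else hi
    lower = j - (step >> 1)
    if lower < lo:
        lower = lo
    while lower < upper:
        mid = (lower + upper) // 2
        if poss[mid] < target:
            lower = mid + 1
        else:
            upper = mid
    return lower


@njit(cache=True)
def reproduce(
    indptr,
    ids,
    poss,
    lws,
    cls,
    sel_indptr,
    parents,
    n_off,
    s_tab,
    h_tab,
    lw_hom,
    mcount,
    mcap,
    chrom_starts,
    n_genes_per_chrom,
    xover_cdf,
    u_gamete,
    bin_cum,
    bin_lo,
    bin_hi,
    bin_h,
    lam,
    out_ids,
    out_poss,
    out_lws,
    out_cls,
    out_indptr,
    out_sel_ids,
    out_sel_poss,
    out_sel_lws,
    out_sel_indptr,
):
    """Build all 2*n_off gametes of the next generation.

    ``xover_cdf`` holds, per chromosome, the cumulative distribution of the
    crossover count (Binomial(boundaries, r), precomputed by the caller).
    Returns (status, total, sel_total, new_mcount); non-OK statuses request
    buffer growth and the generation is retried.
    """
    n_chrom = n_genes_per_chrom.size
    bp = np.empty(512)
    write = 0
    swrite = 0
    cap = out_ids.size
    scap = out_sel_ids.size
    out_indptr[0] = 0
    out_sel_indptr[0] = 0
    for k in range(2 * n_off):
        p = parents[k]
        a = indptr[2 * p]
        a1 = indptr[2 * p + 1]
        b = a1
        b1 = indptr[2 * p + 2]
        if write + (a1 - a) + (b1 - b) + 64 > cap:
            return STATUS_GROW_IDS, write, swrite, mcount
        if swrite + (sel_indptr[2 * p + 2] - sel_indptr[2 * p]) + 64 > scap:
            return STATUS_GROW_SEL, write, swrite, mcount
        # crossover breakpoints: independent assortment between chromosomes,
        # Binomial(boundaries, r) crossovers at uniform boundaries within
        nbp = 0
        for c in range(n_chrom):
            if c > 0 and np.random.random() < 0.5:
                bp[nbp] = chrom_starts[c]
                nbp += 1
            u = np.random.random()
            kx = 0
            while xover_cdf[c, kx] < u:
                kx += 1
            nb = n_genes_per_chrom[c] - 1
            for _ in range(kx):
                if nbp < bp.size:
                    bp[nbp] = chrom_starts[c] + 1.0 + int(np.random.random() * nb)
                    nbp += 1
        if nbp > 24:
            bp[:nbp].sort()
        else:
            for si in range(1, nbp):  # insertion sort for the common case
                v = bp[si]
                sj = si - 1
                while sj >= 0 and bp[sj] > v:
                    bp[sj + 1] = bp[sj]
                    sj -= 1
                bp[sj + 1] = v
        phase = 0 if np.random.random() < 0.5 else 1
        cnt = 0
        scnt = 0
        far = np.float32(1.0e18)
        w2 = write
        for seg in range(nbp + 1):
            seg_end = np.float32(bp[seg]) if seg < nbp else far
            # copy the active run up to the breakpoint; skip the inactive one
            if phase == 0:
                t = a
                while t < a1 and poss[t] < seg_end:
                    out_ids[w2] = ids[t]
                    out_poss[w2] = poss[t]
                    out_lws[w2] = lws[t]
                    out_cls[w2] = cls[t]
                    if cls[t] != 0:
                        out_sel_ids[swrite + scnt] = ids[t]
                        out_sel_poss[swrite + scnt] = poss[t]
                        out_sel_lws[swrite + scnt] = lws[t]
                        scnt += 1
                    w2 += 1
                    t += 1
                a = t
                b = _gallop(poss, b, b1, seg_end)
            else:
                t = b
                while t < b1 and poss[t] < seg_end:
                    out_ids[w2] = ids[t]
                    out_poss[w2] = poss[t]
                    out_lws[w2] = lws[t]
                    out_cls[w2] = cls[t]
                    if cls[t] != 0:
                        out_sel_ids[swrite + scnt] = ids[t]
                        out_sel_poss[swrite + scnt] = poss[t]
                        out_sel_lws[swrite + scnt] = lws[t]
                        scnt += 1
                    w2 += 1
                    t += 1
                b = t
                a = _gallop(poss, a, a1, seg_end)
            phase = 1 - phase
        cnt = w2 - write
        # new mutations: Poisson(u_gamete), s from the discrete mixture
        nnew = np.random.poisson(u_gamete)
        for _ in range(nnew):
            if mcount >= mcap:
                return STATUS_GROW_MUTS, write, swrite, mcount
            gpos = np.float32(np.random.random() * chrom_starts[n_chrom])
            u = np.random.random()
            bidx = 0
            while bidx < 4 and u > bin_cum[bidx]:
                bidx += 1
            s0 = bin_lo[bidx] + np.random.random() * (bin_hi[bidx] - bin_lo[bidx])
            ss = s0 * lam
            if ss > 1.0:
                ss = 1.0
            hh = bin_h[bidx]
            s_tab[mcount] = ss
            h_tab[mcount] = hh
            lwm = np.log(1.0 - ss) if ss < 1.0 else -np.inf
            lwh = np.log(1.0 - ss * hh) if ss * hh < 1.0 else -np.inf
            lw_hom[mcount] = lwm
            selected = np.abs(lwm - 2.0 * lwh) > SEL_CORR_TOL
            ins = _gallop(out_poss, write, write + cnt, gpos)
            for t in range(write + cnt, ins, -1):
                out_ids[t] = out_ids[t - 1]
                out_poss[t] = out_poss[t - 1]
                out_lws[t] = out_lws[t - 1]
                out_cls[t] = out_cls[t - 1]
            out_ids[ins] = mcount
            out_poss[ins] = gpos
            out_lws[ins] = lwh
            out_cls[ins] = 1 if selected else 0
            if selected:
                sins = _gallop(out_sel_poss, swrite, swrite + scnt, gpos)
                for t in range(swrite + scnt, sins, -1):
                    out_sel_ids[t] = out_sel_ids[t - 1]
                    out_sel_poss[t] = out_sel_poss[t - 1]
                    out_sel_lws[t] = out_sel_lws[t - 1]
                out_sel_ids[sins] = mcount
                out_sel_poss[sins] = gpos
                out_sel_lws[sins] = lwh
                scnt += 1
            cnt += 1
            mcount += 1
        write += cnt
        swrite += scnt
        out_indptr[k + 1] = write
        out_sel_indptr[k + 1] = swrite
    return STATUS_OK, write, swrite, mcount


@njit(cache=True)
def count_alleles(indptr, ids, n_hap, counts):
    """Accumulate this population's derived-allele count per mutation index."""
    total = indptr[n_hap]
    for t in range(total):
        counts[ids[t]] += 1


@njit(cache=True)
def remove_fixed(indptr, ids, poss, lws, cls, n_hap, counts):
    """Drop mutations with count == n_hap (fixed here) from the haplotypes."""
    write = 0
    start = 0
    for hseg in range(n_hap):
        end = indptr[hseg + 1]
        for t in range(start, end):
            if counts[ids[t]] != n_hap:
                ids[write] = ids[t]
                poss[write] = poss[t]
                lws[write] = lws[t]
                cls[write] = cls[t]
                write += 1
        start = end
        indptr[hseg + 1] = write
    return write


@njit(cache=True)
def remove_fixed_sel(sel_indptr, sel_ids, sel_poss, sel_lws, n_hap, counts):
    """Companion sweep for the selected-site sidecar arrays."""
    write = 0
    start = 0
    for hseg in range(n_hap):
        end = sel_indptr[hseg + 1]
        for t in range(start, end):
            if counts[sel_ids[t]] != n_hap:
                sel_ids[write] = sel_ids[t]
                sel_poss[write] = sel_poss[t]
                sel_lws[write] = sel_lws[t]
                write += 1
        start = end
        sel_indptr[hseg + 1] = write
    return write
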