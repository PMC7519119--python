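import numpy as np
import pytest

import cnvmqtl as cm


@pytest.fixture(scope="session")
def small_cfg():
    return cm.SimConfig(seed=11, n_samples=40, n_cnvs=20, n_cpgs=40, n_snps=20, n_genes=20)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    """A seeded desk-scale cohort with 8 planted CNV→CpG effects."""
    cnvs = cm.simulate_cnv_genotypes(small_cfg)
    truth = cm.make_truth(cnvs, small_cfg, n_planted=8, n_ld_pairs=5)
    meth = cm.simulate_methylation(cnvs, truth, small_cfg)
    snps = cm.simulate_snps_in_ld(cnvs, truth, small_cfg)
    expr = cm.simulate_expression(meth, cnvs, truth, small_cfg)
    return {"cfg": small_cfg, "cnvs": cnvs, "truth": truth, "meth": meth, "snps": snps, "expr": expr}


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def spearman_bruteforce(x, y):
    """Independent Spearman oracle: explicit average-tie ranks, then the
    summation-formula Pearson correlation.  Shares no code with the package.
    """
    def avg_ranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            mean_rank = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = mean_rank
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    n = len(rx)
    sx, sy = sum(rx), sum(ry)
    sxy = sum(a * b for a, b in zip(rx, ry))
    sxx = sum(a * a for a in rx)
    syy = sum(b * b for b in ry)
    num = n * sxy - sx * sy
    den = ((n * sxx - sx * sx) * (n * syy - sy * sy)) ** 0.5
    return num / den


def pearson_r2_bruteforce(a, b):
    """Summation-formula Pearson r², independent of numpy.corrcoef."""
    n = len(a)
    sa, sb = sum(a), sum(b)
    sab = sum(x * y for x, y in zip(a, b))
    saa = sum(x * x for x in a)
    sbb = sum(y * y for y in b)
    num = n * sab - sa * sb
    den = (n * saa - sa * sa) * (n * sbb - sb * sb)
    return num * num / den
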