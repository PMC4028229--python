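"""Independent brute-force statistical oracles (pure-Python loops)."""

import math


def oracle_cor(a, b):
    d = [x - y for x, y in zip(a, b)]
    n = len(d)
    mean_d = sum(d) / n
    sd = math.sqrt(sum((x - mean_d) ** 2 for x in d) / (n - 1))
    total_mean = (sum(a) + sum(b)) / (2 * n)
    return 2 * sd, 100 * 2 * sd / total_mean


def oracle_icc_anova(a, b):
    """ICC(2,1) from explicit two-way ANOVA sums of squares (loops)."""
    n, k = len(a), 2
    data = [[a[i], b[i]] for i in range(n)]
    grand = sum(sum(row) for row in data) / (n * k)
    row_means = [sum(row) / k for row in data]
    col_means = [sum(data[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_tot = sum((data[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def oracle_paired_t(a, b):
    """Textbook paired t with Student-t two-tailed p (via scipy's CDF)."""
    from scipy.stats import t as tdist
    d = [x - y for x, y in zip(a, b)]
    n = len(d)
    mean_d = sum(d) / n
    sd = math.sqrt(sum((x - mean_d) ** 2 for x in d) / (n - 1))
    t = mean_d / (sd / math.sqrt(n))
    p = 2 * float(tdist.sf(abs(t), n - 1))
    return t, p
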