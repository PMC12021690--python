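"""Brute-force sums-of-squares ICC oracle: explicit loops, no array shortcuts.

Kept deliberately naive and independent of the package implementation so it
can serve as a ground-truth check for the ANOVA-based ICC estimators.
"""


def brute_force_icc(values) -> dict[str, float]:
    """All four ICC forms from first principles on a nested list of scores."""
    n = len(values)
    k = len(values[0])
    total = 0.0
    for i in range(n):
        for r in range(k):
            total += values[i][r]
    grand = total / (n * k)

    row_means = []
    for i in range(n):
        s = 0.0
        for r in range(k):
            s += values[i][r]
        row_means.append(s / k)
    col_means = []
    for r in range(k):
        s = 0.0
        for i in range(n):
            s += values[i][r]
        col_means.append(s / n)

    ssb = 0.0
    for i in range(n):
        ssb += k * (row_means[i] - grand) ** 2
    ssw = 0.0
    for i in range(n):
        for r in range(k):
            ssw += (values[i][r] - row_means[i]) ** 2
    ssj = 0.0
    for r in range(k):
        ssj += n * (col_means[r] - grand) ** 2
    sse = 0.0
    for i in range(n):
        for r in range(k):
            sse += (values[i][r] - row_means[i] - col_means[r] + grand) ** 2

    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    msj = ssj / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    def ratio(num, den):
        if den == 0.0:
            return float("inf") if num > 0 else float("-inf") if num < 0 else float("nan")
        return num / den

    return {
        "ICC1": ratio(msb - msw, msb + (k - 1) * msw),
        "ICC1k": ratio(msb - msw, msb),
        "ICC2": ratio(msb - mse, msb + (k - 1) * mse + k * (msj - mse) / n),
        "ICC2k": ratio(msb - mse, msb + (msj - mse) / n),
    }
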