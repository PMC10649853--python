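"""Independent brute-force oracle for run-based dose-dependent annotation.

Deliberately written against the rules as stated, not against the library:
it enumerates every contiguous dose window and keeps the maximal ones, so
tests can compare it with the production run-finder on exhaustive inputs.
"""


def classify(value, half_width):
    if value > half_width:
        return "up"
    if value < -half_width:
        return "down"
    return "inside"


def brute_force_activities(values, half_width, min_consecutive=2, effect_threshold=0.1):
    """All qualifying (direction, supporting dose indices, peak) by window scan.

    A window [i, j) qualifies when every dose in it is classified on the same
    non-inside side, it cannot be extended on either end, its length is at
    least ``min_consecutive``, and its peak |value| exceeds the effect-size
    threshold.
    """
    n = len(values)
    classes = [classify(v, half_width) for v in values]
    out = []
    for i in range(n):
        for j in range(i + min_consecutive, n + 1):
            window = classes[i:j]
            direction = window[0]
            if direction == "inside" or any(c != direction for c in window):
                continue
            extendable_left = i > 0 and classes[i - 1] == direction
            extendable_right = j < n and classes[j] == direction
            if extendable_left or extendable_right:
                continue
            peak = max(abs(v) for v in values[i:j])
            if peak > effect_threshold:
                out.append((direction, tuple(range(i, j)), peak))
    return sorted(out)
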