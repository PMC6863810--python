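"""Independent brute-force oracles shared by the test modules."""


def oracle_filter(df, rt_min=200.0, rt_max=2000.0, sd_k=2.0):
    """Literal re-statement of the three trial-discard rules.

    (i) drop error trials; (ii) drop RT < rt_min or > rt_max; (iii) per
    trial type, drop RTs beyond sd_k sample SDs from that type's mean of
    the remaining trials, in one pass.  Pure-Python, no pandas filtering —
    independent of the implementation it checks.  Returns retained row
    indices in order.
    """
    keep = []
    for trial_type in ("congruent", "incongruent"):
        rows = [
            (i, r.rt_ms)
            for i, r in df.iterrows()
            if r.congruency == trial_type and bool(r.correct)
            and not (r.rt_ms < rt_min or r.rt_ms > rt_max)
        ]
        if len(rows) >= 2:
            rts = [rt for _, rt in rows]
            mean = sum(rts) / len(rts)
            sd = (sum((x - mean) ** 2 for x in rts) / (len(rts) - 1)) ** 0.5
            rows = [(i, rt) for i, rt in rows if abs(rt - mean) <= sd_k * sd]
        keep += [i for i, _ in rows]
    return sorted(keep)
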