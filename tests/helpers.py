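"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here re-derives term canonical forms, footprints and the five
pruning predicates literally from the TermSpec dataclass fields, without
calling the package's own canonical()/footprint()/apply_checks machinery,
so the two routes stay independent.
"""

import itertools


def oracle_canonical(term):
    if term.kind == "smooth":
        return f"s({term.vars[0]})"
    if term.kind == "linear":
        return f"lin({term.vars[0]})"
    if term.kind == "factor_main":
        return term.factors[0]
    if term.kind == "factor_interaction":
        return ":".join(sorted(term.factors))
    if term.kind == "by_smooth":
        return f"s({term.vars[0]},by={oracle_canonical(term.by_factor)})"
    if term.kind == "tensor_smooth":
        a, b = sorted(term.vars)
        return f"te({a},{b})"
    raise AssertionError(term.kind)


def oracle_footprint(term):
    names = set(term.vars) | set(term.factors)
    if term.by_factor is not None:
        names |= oracle_footprint(term.by_factor)
    return names


def oracle_model_id(terms):
    if not terms:
        return "null"
    return "+".join(sorted(oracle_canonical(t) for t in terms))


def oracle_check(terms, disallowed_pairs, max_predictors):
    """Lowest-numbered violated check for a term combination, or None."""
    if not terms:
        return None
    foot = set()
    for t in terms:
        foot |= oracle_footprint(t)
    if len(foot) > max_predictors:
        return 1

    canons = {oracle_canonical(t) for t in terms}
    for t in terms:
        if t.kind == "by_smooth":
            needed = [oracle_canonical(t.by_factor)]
            if t.by_factor.kind == "factor_interaction":
                needed += list(t.by_factor.factors)
            if any(r not in canons for r in needed):
                return 2

    singles = {t.vars[0] for t in terms if t.kind in ("smooth", "linear")}
    if any(t.vars[0] in singles for t in terms if t.kind == "by_smooth"):
        return 3
    te_vars = set()
    for t in terms:
        if t.kind == "tensor_smooth":
            te_vars |= set(t.vars)
    if te_vars & singles:
        return 4

    for a, b in itertools.combinations(sorted(foot), 2):
        if frozenset((a, b)) in disallowed_pairs:
            return 5
    return None


def oracle_candidate_ids(terms, max_predictors, disallowed_pairs=frozenset()):
    """Surviving model ids from power-set enumeration + literal filters."""
    keep = {"null"}
    removed = {}
    seen = set()
    for size in range(1, max_predictors + 1):
        for combo in itertools.combinations(terms, size):
            mid = oracle_model_id(combo)
            if mid in seen:
                continue
            seen.add(mid)
            check = oracle_check(combo, disallowed_pairs, max_predictors)
            if check is None:
                keep.add(mid)
            else:
                removed[mid] = check
    return keep, removed
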