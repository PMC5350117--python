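"""Naive per-site enumeration oracle for the concordance metric suite.

Deliberately independent of the package implementation: the join is a plain
dict walk and every metric is a counted Fraction — no confusion matrix, no
numpy.  Used to cross-check compute_metrics on random callset pairs.
"""

from fractions import Fraction

from panelval.concordance import GenotypeClass as G

NONREF = (G.HET, G.HOM_ALT)


def oracle_join(truth, eval_, targets):
    """Union of recorded sites inside targets; absence -> hom-ref inside a
    callset's assessed regions, missing outside."""
    def lookup(cs, key):
        if key in cs.calls:
            return cs.calls[key]
        if cs.assessed_regions.contains(key.chrom, key.pos):
            return G.HOM_REF
        return G.MISSING

    pairs = []
    for key in set(truth.calls) | set(eval_.calls):
        if len(key.ref) != 1 or len(key.alt) != 1:
            continue
        if not targets.contains(key.chrom, key.pos):
            continue
        pairs.append((lookup(truth, key), lookup(eval_, key)))
    return pairs


def oracle_metrics(pairs):
    """Metric suite by direct enumeration; None marks 0/0."""
    both_called = concordant = concordant_homref = 0
    truth_nonref = nrs_num = nrgc_num = 0
    tp = fp = fn = 0
    for t, e in pairs:
        t_called = t is not G.MISSING
        e_called = e is not G.MISSING
        if t_called and e_called:
            both_called += 1
            if t is e:
                concordant += 1
                if t is G.HOM_REF:
                    concordant_homref += 1
        if t in NONREF:
            truth_nonref += 1
            if e in NONREF:
                nrs_num += 1
            if e is t:
                nrgc_num += 1
            if e is G.HOM_REF or e is G.MISSING:
                fn += 1
        if e in NONREF:
            if t in NONREF:
                tp += 1
            elif t is G.HOM_REF:
                fp += 1

    def frac(num, den):
        return None if den == 0 else Fraction(num, den)

    fp_rate = frac(fp, tp + fp)
    return {
        "tp": tp, "fp": fp, "fn": fn,
        "ogc": frac(concordant, both_called),
        "nrs": frac(nrs_num, truth_nonref),
        "nrd": frac(both_called - concordant,
                    both_called - concordant_homref),
        "nrgc": frac(nrgc_num, truth_nonref),
        "precision": frac(tp, tp + fp),
        "sensitivity": frac(tp, tp + fn),
        "specificity": None if fp_rate is None else 1 - fp_rate,
        "fp_rate": fp_rate,
        "fn_rate": frac(fn, tp + fn),
    }


def random_callset_pair(rng, max_sites=30):
    """A random truth/evaluation callset pair over one small region."""
    from panelval.concordance import CallSet, VariantKey
    from panelval.regions import RegionIndex, TargetRegion

    region = TargetRegion("chrT", 0, 500, "G1", 1)
    index = RegionIndex([region])
    n = int(rng.integers(0, max_sites + 1))
    positions = rng.choice(400, size=n, replace=False) + 1
    classes = [G.HOM_REF, G.HET, G.HOM_ALT, G.MISSING]
    truth_calls, eval_calls = {}, {}
    for pos in positions:
        key = VariantKey("chrT", int(pos), "A", "C")
        t = classes[int(rng.integers(0, 4))]
        e = classes[int(rng.integers(0, 4))]
        # record a site in a callset with prob 0.8, else rely on absence
        if t is not G.HOM_REF or rng.random() < 0.5:
            truth_calls[key] = t
        if e is not G.HOM_REF or rng.random() < 0.5:
            eval_calls[key] = e
    truth = CallSet("T", truth_calls, index)
    eval_ = CallSet("E", eval_calls, index)
    return truth, eval_, index
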