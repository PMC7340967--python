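"""Independent brute-force reference implementations for the encoders,
metrics and AUC.  Deliberately written with plain Python loops and dicts,
sharing no code with the package internals, so they can serve as oracles.
"""

from itertools import product
from math import sqrt

ALPHABET = "ACGU"


def lex_kmers(k):
    return ["".join(p) for p in product(ALPHABET, repeat=k)]


def oracle_kmer(seq, k, counts=False):
    n_place = len(seq) - k + 1
    tally = {m: 0 for m in lex_kmers(k)}
    for i in range(n_place):
        tally[seq[i:i + k]] += 1
    return [tally[m] if counts else tally[m] / n_place for m in lex_kmers(k)]


def oracle_enac(seq, win=5):
    out = []
    for start in range(len(seq) - win + 1):
        chunk = seq[start:start + win]
        for b in ALPHABET:
            out.append(chunk.count(b) / win)
    return out


def oracle_xxkgap(seq, family, kgap):
    kl, kr = {"mM": (1, 1), "mD": (1, 2), "dM": (2, 1)}[family]
    out = []
    for g in range(1, kgap + 1):
        tally = {(a, b): 0 for a in lex_kmers(kl) for b in lex_kmers(kr)}
        width = kl + g + kr
        n_place = len(seq) - width + 1
        for i in range(n_place):
            left = seq[i:i + kl]
            right = seq[i + kl + g:i + kl + g + kr]
            tally[(left, right)] += 1
        for a in lex_kmers(kl):
            for b in lex_kmers(kr):
                out.append(tally[(a, b)] / n_place)
    return out


def oracle_psp_fit(pos_seqs, neg_seqs, k):
    """Z as nested dict: Z[kmer][position] = freq+ - freq-."""
    L = len(pos_seqs[0])
    Z = {}
    for m in lex_kmers(k):
        Z[m] = {}
        for j in range(L - k + 1):
            fp = sum(1 for s in pos_seqs if s[j:j + k] == m) / len(pos_seqs)
            fn = sum(1 for s in neg_seqs if s[j:j + k] == m) / len(neg_seqs)
            Z[m][j] = fp - fn
    return Z


def oracle_psp_encode(seq, Z, k):
    return [Z[seq[j:j + k]][j] for j in range(len(seq) - k + 1)]


EIIP = {"A": 0.1260, "C": 0.1340, "G": 0.0806, "U": 0.1335}


def oracle_eiip(seq):
    return [EIIP[b] for b in seq]


def oracle_pseeiip(seq):
    freqs = oracle_kmer(seq, 3)
    return [(EIIP[m[0]] + EIIP[m[1]] + EIIP[m[2]]) * f
            for m, f in zip(lex_kmers(3), freqs)]


def standardize_table(table):
    """table: dict property -> dict dinuc -> value; population z-scores."""
    out = {}
    for prop, vals in table.items():
        xs = [vals[d] for d in lex_kmers(2)]
        mu = sum(xs) / 16
        sd = sqrt(sum((x - mu) ** 2 for x in xs) / 16)
        out[prop] = {d: (vals[d] - mu) / sd for d in lex_kmers(2)}
    return out


def oracle_pc_psednc(seq, lam, w, table):
    """table: dict property -> dict dinuc -> raw value (standardized here)."""
    std = standardize_table(table)
    props = list(std)

    def theta_pair(da, db):
        return sum((std[p][da] - std[p][db]) ** 2 for p in props) / len(props)

    dinucs = [seq[i:i + 2] for i in range(len(seq) - 1)]
    thetas = []
    for g in range(1, lam + 1):
        pairs = [theta_pair(dinucs[i], dinucs[i + g])
                 for i in range(len(dinucs) - g)]
        thetas.append(sum(pairs) / len(pairs))
    freqs = oracle_kmer(seq, 2)
    denom = sum(freqs) + w * sum(thetas)
    return [f / denom for f in freqs] + [w * t / denom for t in thetas]


def oracle_be(seq):
    out = []
    for b in seq:
        for a in ALPHABET:
            out.append(1.0 if b == a else 0.0)
    return out


def oracle_ncp_nd(seq):
    out = []
    for i, b in enumerate(seq):
        out.append(1.0 if b in "AG" else 0.0)
        out.append(1.0 if b in "AC" else 0.0)
        out.append(1.0 if b in "AU" else 0.0)
        out.append(seq[:i + 1].count(b) / (i + 1))
    return out


def oracle_contingency(y_true, y_pred):
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 0)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
    return tp, tn, fp, fn


def oracle_metrics(y_true, y_pred):
    tp, tn, fp, fn = oracle_contingency(y_true, y_pred)
    sn = tp / (tp + fn)
    sp = tn / (tn + fp)
    acc = (tp + tn) / (tp + tn + fp + fn)
    denom = sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom
    return sn, sp, acc, mcc


def mcc_missrate_form(n_pos, n_neg, n_fn, n_fp):
    """MCC written in terms of class sizes and per-class miss counts."""
    num = 1.0 - (n_fn / n_pos + n_fp / n_neg)
    den = sqrt((1.0 + (n_fp - n_fn) / n_pos) * (1.0 + (n_fn - n_fp) / n_neg))
    return num / den


def oracle_auc_mannwhitney(scores, y_true):
    """Normalized Mann-Whitney U: P(score+ > score-) + 0.5 P(tie)."""
    pos = [s for s, t in zip(scores, y_true) if t == 1]
    neg = [s for s, t in zip(scores, y_true) if t == 0]
    u = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                u += 1.0
            elif p == n:
                u += 0.5
    return u / (len(pos) * len(neg))


def random_window(rng, length=41, center_c=True):
    seq = "".join(rng.choice(list(ALPHABET)) for _ in range(length))
    if center_c:
        mid = length // 2
        seq = seq[:mid] + "C" + seq[mid + 1:]
    return seq
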