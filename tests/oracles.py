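"""Independent brute-force oracles used to validate the pipeline's
algorithms.  Each one re-derives the expected answer by exhaustive
scanning or enumeration, sharing no code with the implementation paths
it checks."""

import math

import numpy as np

from capriseq.models import TranscriptModel


# ------------------------------------------------- loci clustering oracle

def random_transcripts(rng, n):
    out = []
    for i in range(n):
        start = int(rng.integers(0, 5000))
        n_ex = int(rng.integers(1, 4))
        exons = []
        pos = start
        for _ in range(n_ex):
            ln = int(rng.integers(50, 400))
            exons.append((pos, pos + ln))
            pos += ln + int(rng.integers(30, 300))
        out.append(TranscriptModel(
            f"t{i}", f"chr{int(rng.integers(1, 3))}",
            "+" if rng.random() < 0.7 else "-", exons))
    return out


def brute_force_loci(transcripts, link):
    """Connected components over an all-pairs scan of the link relation."""
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(range(len(transcripts)))
    for i in range(len(transcripts)):
        for j in range(i + 1, len(transcripts)):
            if link(transcripts[i], transcripts[j]):
                g.add_edge(i, j)
    return {frozenset(transcripts[i].transcript_id for i in comp)
            for comp in nx.connected_components(g)}


# ------------------------------------------------------ AS events oracle

def oracle_pair_events(x, y):
    """Naive re-derivation of the pairwise AS event definitions."""
    out = set()
    strand = x.strand

    def donor(iv):
        return iv[0] if strand == "+" else iv[1]

    def acceptor(iv):
        return iv[1] if strand == "+" else iv[0]

    es_members = set()
    for a, b in ((x, y), (y, x)):
        ca, cb = a.intron_chain, b.intron_chain
        for ib in cb:
            idx = [i for i, ia in enumerate(ca)
                   if ib[0] <= ia[0] and ia[1] <= ib[1]]
            if len(idx) >= 2 and idx == list(range(idx[0], idx[-1] + 1)) \
                    and ca[idx[0]][0] == ib[0] and ca[idx[-1]][1] == ib[1]:
                for i in idx[:-1]:
                    out.add(("ES", (ca[i][1], ca[i + 1][0])))
                es_members.update({(ca[idx[0]], ib), (ib, ca[idx[0]]),
                                   (ca[idx[-1]], ib), (ib, ca[idx[-1]])})
        for ia in ca:
            if ia in cb:
                continue
            if any(es <= ia[0] and ia[1] <= ee for es, ee in b.exons):
                out.add(("IR", ia))
    for ia in x.intron_chain:
        for ib in y.intron_chain:
            if ia == ib or (ia, ib) in es_members:
                continue
            if donor(ia) == donor(ib) and acceptor(ia) != acceptor(ib):
                out.add(("AA", (donor(ia),) + tuple(sorted((acceptor(ia),
                                                            acceptor(ib))))))
            if acceptor(ia) == acceptor(ib) and donor(ia) != donor(ib):
                out.add(("AD", (acceptor(ia),) + tuple(sorted((donor(ia),
                                                               donor(ib))))))
    return out


def random_locus(rng):
    """Up to 4 isoforms derived from one base chain, mirroring real loci."""
    n_ex = int(rng.integers(2, 6))
    exons = []
    pos = 0
    for _ in range(n_ex):
        exons.append((pos, pos + int(rng.integers(50, 200))))
        pos = exons[-1][1] + int(rng.integers(50, 200))
    strand = "+" if rng.random() < 0.5 else "-"
    isoforms = [TranscriptModel("t0", "chr1", strand, exons)]
    for k in range(int(rng.integers(1, 4))):
        ex = [list(e) for e in exons]
        op = rng.random()
        if op < 0.3 and len(ex) >= 3:
            del ex[int(rng.integers(1, len(ex) - 1))]
        elif op < 0.55 and len(ex) >= 2:
            i = int(rng.integers(0, len(ex) - 1))
            ex[i + 1][0] += int(rng.integers(5, 30))
        elif op < 0.8 and len(ex) >= 2:
            i = int(rng.integers(0, len(ex) - 1))
            ex[i][1] -= int(rng.integers(5, 30))
        elif len(ex) >= 2:
            i = int(rng.integers(0, len(ex) - 1))
            ex[i] = [ex[i][0], ex[i + 1][1]]
            del ex[i + 1]
        isoforms.append(TranscriptModel(f"t{k + 1}", "chr1", strand,
                                        [tuple(e) for e in ex]))
    return isoforms


# ------------------------------------------------------------ ORF oracle

def oracle_orfs(seq, min_aa):
    """Exhaustive per-position 3-frame re-scan."""
    seq = seq.upper()
    stops = {"TAA", "TAG", "TGA"}
    found = set()
    for frame in range(3):
        codon_starts = list(range(frame, len(seq) - 2, 3))
        stop_positions = [i for i in codon_starts if seq[i:i + 3] in stops]
        first_stop = stop_positions[0] if stop_positions else None
        lead_end = (first_stop + 3 if first_stop is not None
                    else len(seq) - (len(seq) - frame) % 3)
        if seq[frame:frame + 3] != "ATG":
            aa = (lead_end - frame) // 3 - (1 if first_stop is not None else 0)
            if aa >= min_aa:
                found.add((frame, frame, lead_end))
        for i in codon_starts:
            if seq[i:i + 3] != "ATG":
                continue
            nxt = next((s for s in stop_positions if s >= i), None)
            if nxt is not None:
                if (nxt - i) // 3 >= min_aa:
                    found.add((frame, i, nxt + 3))
            else:
                end = len(seq) - (len(seq) - i) % 3
                if (end - i) // 3 >= min_aa:
                    found.add((frame, i, end))
    return found


# ---------------------------------------------------- hypergeometric tail

def brute_force_hypergeom_tail(N, K, n, k):
    """P(X >= k) by summing the exact combinatorial mass."""
    total = math.comb(N, n)
    acc = 0
    for x in range(k, min(K, n) + 1):
        acc += math.comb(K, x) * math.comb(N - K, n - x)
    return acc / total
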