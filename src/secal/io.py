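"""Readers and writers for the package's on-disk dialects.

Trees travel as Newick (branch lengths = durations for chronograms,
substitutions/site for substitution trees) or NEXUS; alignments as FASTA;
MCMC traces and node summaries as tab-separated text.  Summary trees can be
written as NEXUS with BEAST-style comment annotations
``[&median=..,hpd={lo,hi}]`` on internal nodes.

Node/branch columns in trace files are labelled by a compact deterministic
clade key (``<smallest tip>|<clade size>|<crc32 of sorted tips>``); the full
tip sets are recorded in ``#clade`` header comments so a trace file is
self-contained.
"""

from __future__ import annotations

import re
import zlib
from pathlib import Path

import dendropy
import numpy as np
import yaml
from Bio import SeqIO

from .calibrate import CalibrationPrior
from .dating import NodeSummary, Trace
from .seqsim import NUC, Alignment
from .treesim import SubstTree, TimeTree

__all__ = [
    "clade_key_str",
    "write_newick",
    "read_timetree_newick",
    "write_nexus_trees",
    "write_fasta",
    "read_fasta",
    "write_trace",
    "read_trace",
    "write_summaries",
    "read_summaries",
    "write_annotated_nexus",
    "read_annotated_nexus",
    "write_calibrations_yaml",
    "read_calibrations_yaml",
]


def clade_key_str(key: frozenset) -> str:
    tips = sorted(key)
    crc = zlib.crc32("|".join(tips).encode()) & 0xFFFFFFFF
    return f"{tips[0]}|{len(tips)}|{crc:08x}"


# -- trees -------------------------------------------------------------------


def write_newick(tree: TimeTree | SubstTree, path) -> None:
    Path(path).write_text(tree.newick() + "\n")


def _timetree_from_dendropy(dtree: dendropy.Tree) -> TimeTree:
    dtree.calc_node_ages(ultrametricity_precision=1e-6)
    nodes = list(dtree.preorder_node_iter())
    tips = [nd for nd in nodes if nd.is_leaf()]
    internals = [nd for nd in nodes if not nd.is_leaf()]
    idx = {id(nd): i for i, nd in enumerate(tips)}
    idx.update({id(nd): len(tips) + i for i, nd in enumerate(internals)})
    m = len(nodes)
    parent = np.full(m, -1, dtype=np.int64)
    children = np.full((m, 2), -1, dtype=np.int64)
    ages = np.zeros(m)
    for nd in nodes:
        i = idx[id(nd)]
        ages[i] = max(nd.age, 0.0)
        ch = nd.child_nodes()
        if ch:
            if len(ch) != 2:
                raise ValueError("tree must be fully bifurcating")
            children[i, 0] = idx[id(ch[0])]
            children[i, 1] = idx[id(ch[1])]
            parent[children[i, 0]] = i
            parent[children[i, 1]] = i
    ages[: len(tips)] = 0.0
    labels = [nd.taxon.label.replace(" ", "_") for nd in tips]
    return TimeTree(parent, children, ages, labels)


def read_timetree_newick(path) -> TimeTree:
    """Parse an ultrametric Newick chronogram (branch lengths = durations)."""
    dtree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    return _timetree_from_dendropy(dtree)


def write_nexus_trees(trees: dict, path) -> None:
    """Write ``{name: TimeTree|SubstTree}`` as a NEXUS trees block."""
    lines = ["#NEXUS", "begin trees;"]
    for name, t in trees.items():
        lines.append(f"    tree {name} = [&R] {t.newick()}")
    lines.append("end;")
    Path(path).write_text("\n".join(lines) + "\n")


# -- alignments --------------------------------------------------------------


def write_fasta(alignment: Alignment, path) -> None:
    with open(path, "w") as fh:
        for i, label in enumerate(alignment.labels):
            fh.write(f">{label}\n")
            seq = "".join(NUC[s] for s in alignment.seqs[i])
            for j in range(0, len(seq), 80):
                fh.write(seq[j : j + 80] + "\n")


_CODE = {c: i for i, c in enumerate(NUC)}


def read_fasta(path) -> Alignment:
    labels, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        labels.append(rec.id)
        seq = str(rec.seq).upper()
        try:
            rows.append([_CODE[c] for c in seq])
        except KeyError as e:
            raise ValueError(f"non-ACGT state {e} in {rec.id}") from None
    if not labels:
        raise ValueError(f"no sequences in {path}")
    return Alignment(labels, np.array(rows, dtype=np.int8))


# -- traces ------------------------------------------------------------------


def write_trace(trace: Trace, path) -> None:
    with open(path, "w") as fh:
        seen = set()
        for key in [*trace.node_keys, *trace.rate_keys]:
            if key not in seen:
                seen.add(key)
                fh.write(f"#clade\t{clade_key_str(key)}\t{';'.join(sorted(key))}\n")
        cols = (
            ["generation", "loglik", "logprior", "kappa", "freqA", "freqC", "freqG",
             "freqT", "mu_log", "sd_log", "birth_rate"]
            + [f"age_{clade_key_str(k)}" for k in trace.node_keys]
            + [f"rate_{clade_key_str(k)}" for k in trace.rate_keys]
        )
        fh.write("\t".join(cols) + "\n")
        for i in range(trace.n_samples):
            row = [
                str(int(trace.generations[i])),
                repr(float(trace.loglik[i])),
                repr(float(trace.logprior[i])),
                repr(float(trace.kappa[i])),
                *(repr(float(x)) for x in trace.freqs[i]),
                repr(float(trace.mu_log[i])),
                repr(float(trace.sd_log[i])),
                repr(float(trace.birth_rate[i])),
                *(repr(float(x)) for x in trace.node_ages[i]),
                *(repr(float(x)) for x in trace.rates[i]),
            ]
            fh.write("\t".join(row) + "\n")


def read_trace(path) -> Trace:
    key_by_str = {}
    header = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#clade\t"):
                _, ks, tips = line.split("\t")
                key_by_str[ks] = frozenset(tips.split(";"))
            elif header is None:
                header = line.split("\t")
            elif line:
                rows.append(line.split("\t"))
    if header is None or not rows:
        raise ValueError(f"empty or malformed trace file {path}")
    data = np.array(rows, dtype=float)
    cols = {name: j for j, name in enumerate(header)}
    age_cols = [(j, name[4:]) for j, name in enumerate(header) if name.startswith("age_")]
    rate_cols = [(j, name[5:]) for j, name in enumerate(header) if name.startswith("rate_")]
    return Trace(
        generations=data[:, cols["generation"]].astype(np.int64),
        loglik=data[:, cols["loglik"]],
        logprior=data[:, cols["logprior"]],
        kappa=data[:, cols["kappa"]],
        freqs=data[:, [cols["freqA"], cols["freqC"], cols["freqG"], cols["freqT"]]],
        mu_log=data[:, cols["mu_log"]],
        sd_log=data[:, cols["sd_log"]],
        birth_rate=data[:, cols["birth_rate"]],
        node_keys=[key_by_str[s] for _, s in age_cols],
        node_ages=data[:, [j for j, _ in age_cols]],
        rate_keys=[key_by_str[s] for _, s in rate_cols],
        rates=data[:, [j for j, _ in rate_cols]],
    )


# -- node summaries ----------------------------------------------------------


def write_summaries(summaries: dict, path) -> None:
    """Write ``{clade key: NodeSummary}`` as TSV."""
    with open(path, "w") as fh:
        fh.write("key\tn_tips\ttips\tmedian\thpd_lo\thpd_hi\tci_width\n")
        for key in sorted(summaries, key=lambda k: (len(k), sorted(k))):
            s = summaries[key]
            fh.write(
                f"{clade_key_str(key)}\t{len(key)}\t{';'.join(sorted(key))}\t"
                f"{s.median!r}\t{s.hpd_lo!r}\t{s.hpd_hi!r}\t{s.ci_width!r}\n"
            )


def read_summaries(path) -> dict:
    out = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 7:
                continue
            key = frozenset(parts[2].split(";"))
            out[key] = NodeSummary(
                key=key, median=float(parts[3]), hpd_lo=float(parts[4]), hpd_hi=float(parts[5])
            )
    return out


# -- annotated summary trees -------------------------------------------------


def write_annotated_nexus(tree: TimeTree, summaries: dict, path, name: str = "summary") -> None:
    """NEXUS tree whose internal nodes carry ``[&median=..,hpd={lo,hi}]``."""

    def rec(v: int) -> str:
        if tree.is_tip(v):
            s = tree.tip_labels[v]
        else:
            a, b = tree.children[v]
            s = f"({rec(int(a))},{rec(int(b))})"
            summ = summaries.get(tree.clades[v])
            if summ is not None:
                s += f"[&median={summ.median!r},hpd={{{summ.hpd_lo!r},{summ.hpd_hi!r}}}]"
        if v == tree.root:
            return s
        dur = tree.ages[tree.parent[v]] - tree.ages[v]
        return f"{s}:{dur:.12g}"

    text = "#NEXUS\nbegin trees;\n" f"    tree {name} = [&R] {rec(tree.root)};\n" "end;\n"
    Path(path).write_text(text)


_ANNOT_RE = re.compile(r"&median=([^,]+),hpd=\{([^,]+),([^}]+)\}")


def read_annotated_nexus(path) -> tuple[TimeTree, dict]:
    """Recover the chronogram and its node annotations."""
    dtree = dendropy.Tree.get(
        path=str(path), schema="nexus", preserve_underscores=True,
        suppress_internal_node_taxa=True, extract_comment_metadata=False,
    )
    annot = {}
    for nd in dtree.preorder_node_iter():
        for comment in nd.comments:
            m = _ANNOT_RE.search(comment)
            if m:
                tips = frozenset(l.taxon.label.replace(" ", "_") for l in nd.leaf_iter())
                annot[tips] = NodeSummary(
                    key=tips, median=float(m.group(1)),
                    hpd_lo=float(m.group(2)), hpd_hi=float(m.group(3)),
                )
    return _timetree_from_dendropy(dtree), annot


# -- calibrations ------------------------------------------------------------


def write_calibrations_yaml(cals: list, path) -> None:
    data = [c.to_dict() for c in cals]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_calibrations_yaml(path) -> list:
    data = yaml.safe_load(Path(path).read_text())
    return [CalibrationPrior.from_dict(d) for d in data]
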