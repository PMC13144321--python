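"""Synthetic interactomes, multi-view omics and assay tables with planted truth.

The generators emulate the statistical structure of a two-genotype
(WT / knockout), four-treatment (untreated / two single drugs /
combination) cell-line study profiled by RNA-seq, TMT proteomics and
phosphoproteomics: three latent factors (treatment-shared,
combination-specific, genotype), negative-binomial mRNA counts, Gaussian
log-abundances with intensity-dependent missingness, and phosphosite
levels coupled to their parent protein.  Every generator is
bit-reproducible given its parameters and seed, and the planted truth
(receptor->effector paths, a convergence hub shared by two paths, factor
feature support, TF activities, responsive kinases) gives each
downstream stage a recoverable answer.
"""

from __future__ import annotations

import math
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .types import (
    GENOTYPES,
    OmicsView,
    PlantedTruth,
    TREATMENTS,
    ViabilityTrace,
    validate_graph,
)

_NB_DISPERSION = 0.05  # gamma-Poisson over-dispersion for mRNA counts


def generate_network(n_nodes: int, edges_per_node: int, seed: int) -> nx.Graph:
    """Preferential-attachment interactome with uniform(0.3, 1] confidences.

    Returns a simple connected graph whose nodes are protein ids
    ``P0000``.. and whose edges carry a ``confidence`` attribute.
    """
    if n_nodes < 10 or edges_per_node < 1:
        raise ValueError("need n_nodes >= 10 and edges_per_node >= 1")
    rng = np.random.default_rng(seed)
    ba = nx.barabasi_albert_graph(n_nodes, edges_per_node, seed=int(rng.integers(2**31)))
    mapping = {i: f"P{i:04d}" for i in ba.nodes()}
    graph = nx.relabel_nodes(ba, mapping)
    for u, v in sorted(graph.edges()):
        graph[u][v]["confidence"] = float(rng.uniform(0.3, 1.0))
    # BA graphs are connected by construction; keep the invariant anyway
    if not nx.is_connected(graph):
        giant = max(nx.connected_components(graph), key=len)
        graph = graph.subgraph(giant).copy()
    validate_graph(graph)
    return graph


def _two_paths_through_hub(graph: nx.Graph, hub, length: int, rng) -> Optional[list]:
    """Two node-disjoint-except-hub paths of `length` edges crossing `hub`."""
    a = length // 2
    b = length - a
    sp = nx.single_source_shortest_path(graph, hub, cutoff=max(a, b))
    at_a = [n for n, p in sp.items() if len(p) - 1 == a]
    at_b = [n for n, p in sp.items() if len(p) - 1 == b]
    rng.shuffle(at_a)
    rng.shuffle(at_b)
    for r1 in at_a:
        left1 = sp[r1][::-1]  # r1 .. hub
        for e1 in at_b:
            right1 = sp[e1]  # hub .. e1
            if set(left1[:-1]) & set(right1[1:]):
                continue
            path1 = left1[:-1] + right1
            for r2 in at_a:
                left2 = sp[r2][::-1]
                if set(left2[:-1]) & set(path1):
                    continue
                for e2 in at_b:
                    right2 = sp[e2]
                    if set(right2[1:]) & (set(path1) | set(left2[:-1])):
                        continue
                    path2 = left2[:-1] + right2
                    return [path1, path2]
    return None


def plant_truth(
    graph: nx.Graph,
    n_receptors: int = 3,
    n_paths: int = 3,
    path_length: int = 4,
    seed: int = 0,
    support_mode: str = "shared",
) -> PlantedTruth:
    """Plant receptor->effector signaling paths and factor feature support.

    The first two paths share an interior convergence hub; edge
    confidences along every planted path are raised to >= 0.9 so
    propagation and flow can recover them.  ``support_mode='shared'``
    spreads each factor's support over all three views (path-1 nodes for
    the treatment factor, path-2 for the combination factor, path-3 /
    receptors for the genotype factor); ``'view_confined'`` puts factor
    k's support exclusively in view k (mrna, protein, phospho).
    """
    if path_length < 2:
        raise ValueError("path_length must be >= 2")
    if not nx.is_connected(graph):
        raise ValueError("graph must be connected")
    if n_paths < 2:
        raise ValueError("need n_paths >= 2 to plant a convergence hub")
    rng = np.random.default_rng(seed)
    nodes = sorted(graph.nodes())

    hubs = [n for n in nodes if graph.degree(n) >= 2]
    rng.shuffle(hubs)
    paths = None
    hub = None
    for cand in hubs[:200]:
        got = _two_paths_through_hub(graph, cand, path_length, rng)
        if got is not None:
            hub, paths = cand, got
            break
    if paths is None:
        raise RuntimeError(
            f"could not plant two length-{path_length} paths through a shared hub"
        )

    used = set(paths[0]) | set(paths[1])
    for _ in range(n_paths - 2):
        for _attempt in range(200):
            start = nodes[rng.integers(len(nodes))]
            sp = nx.single_source_shortest_path(graph, start, cutoff=path_length)
            targets = [n for n, p in sp.items() if len(p) - 1 == path_length]
            rng.shuffle(targets)
            ok = None
            for t in targets:
                if len(set(sp[t]) & used) == 0:
                    ok = sp[t]
                    break
            if ok is not None:
                paths.append(ok)
                used |= set(ok)
                break

    receptors = {p[0] for p in paths}
    extra = [n for n in nodes if n not in used]
    rng.shuffle(extra)
    while len(receptors) < n_receptors and extra:
        receptors.add(extra.pop())
    tfs = {p[-1] for p in paths}
    kinases = {n for p in paths for n in p[1:-1]}

    for p in paths:
        for u, v in zip(p[:-1], p[1:]):
            graph[u][v]["confidence"] = max(
                graph[u][v]["confidence"], float(rng.uniform(0.9, 1.0))
            )

    # phosphosite dialect PROTEIN_RESIDUE_POSITION, 1-based
    site_nodes = sorted(kinases | tfs | receptors)
    others = [n for n in nodes if n not in site_nodes]
    rng.shuffle(others)
    site_nodes += others[: max(0, int(0.5 * len(nodes)) - len(site_nodes))]
    residues = np.array(["S", "T", "Y"])
    site_map = {}
    for n in sorted(site_nodes):
        pos = int(rng.integers(1, 400))
        site_map[f"{n}_{residues[rng.integers(3)]}{pos}"] = n
    sites_of = {}
    for s, n in site_map.items():
        sites_of.setdefault(n, []).append(s)

    def signed(members, view):
        if view == "phospho":
            feats = [s for m in members for s in sites_of.get(m, [])]
        else:
            feats = list(members)
        # receptors respond upward (surface-receptor induction), other
        # support features get random signs
        return {f: (1.0 if f in receptors or site_map.get(f) in receptors
                    else float(rng.choice([-1.0, 1.0])))
                for f in sorted(feats)}

    background = [n for n in nodes if n not in used]
    rng.shuffle(background)
    # view-confined designs concentrate each factor's whole feature
    # budget in a single view, so their pools are denser
    n_bg = max(3, len(nodes) // (6 if support_mode == "view_confined" else 12))
    bg = [background[i * n_bg : (i + 1) * n_bg] for i in range(3)]

    factor_support: dict = {}
    if support_mode == "view_confined":
        # the genotype factor lives in the phospho view: its pool must
        # consist of site-bearing proteins
        with_sites = [n for n in background[2 * n_bg:] if n in sites_of]
        bg3 = with_sites[:n_bg]
        pool3 = sorted(({p for p in paths[min(2, len(paths) - 1)]
                         if p in sites_of} | set(bg3)))
        pools = [sorted(set(paths[0]) | set(bg[0])),
                 sorted(set(paths[1]) | set(bg[1])),
                 pool3]
        for k, view in zip((1, 2, 3), ("mrna", "protein", "phospho")):
            factor_support[k] = {view: signed(pools[k - 1], view)}
    elif support_mode == "shared":
        pools = [sorted(set(paths[0]) | set(bg[0])),
                 sorted(set(paths[1]) | set(bg[1])),
                 sorted(set(paths[min(2, len(paths) - 1)]) | receptors | set(bg[2]))]
        # keep factor supports disjoint so the latent axes stay identifiable
        seen: set = set()
        clean = []
        for pool in pools:
            clean.append([n for n in pool if n not in seen])
            seen |= set(pool)
        for k in (1, 2, 3):
            factor_support[k] = {v: signed(clean[k - 1], v)
                                 for v in ("mrna", "protein", "phospho")}
    else:
        raise ValueError(f"unknown support_mode {support_mode!r}")

    tf_list = sorted(tfs)
    planted_tf_activity = {tf: (1.0 if i % 2 == 0 else -1.0)
                           for i, tf in enumerate(tf_list)}

    # unit-signed true effects; realized log-fold change = sign * effect_size
    planted_de = {
        "treated_vs_untreated": dict(factor_support[1].get("mrna", {})),
        "combination_vs_rest": dict(factor_support[2].get("mrna", {})),
        "KO_vs_WT": dict(factor_support[3].get("mrna", {})),
    }

    truth = PlantedTruth(
        receptors=receptors,
        tfs=tfs,
        kinases=kinases,
        planted_paths=paths,
        convergence_hubs={hub},
        factor_support=factor_support,
        planted_tf_activity=planted_tf_activity,
        planted_de=planted_de,
        support_mode=support_mode,
    )
    truth.nodes = nodes
    truth.site_map = site_map
    return truth


def generate_annotations(
    graph: nx.Graph,
    truth: PlantedTruth,
    n_terms: int = 500,
    terms_per_node: int = 8,
    seed: int = 0,
) -> dict:
    """Functional term sets; nodes on one planted path share >= 2/3 of theirs.

    Sharing ceil(2t/3) fixed path-specific terms guarantees pairwise
    Jaccard >= 0.5 among same-path nodes, while background nodes draw all
    terms uniformly (expected pairwise Jaccard ~ terms_per_node / n_terms).
    """
    if n_terms < terms_per_node:
        raise ValueError("n_terms must be >= terms_per_node")
    rng = np.random.default_rng(seed)
    terms = [f"T{i:05d}" for i in range(n_terms)]
    ann: dict = {}
    for n in sorted(graph.nodes()):
        ann[n] = set(rng.choice(terms, size=terms_per_node, replace=False))
    n_shared = math.ceil(2 * terms_per_node / 3)
    cores: dict = {}
    for p in truth.planted_paths:
        pool = list(rng.choice(terms, size=terms_per_node, replace=False))
        core = set(pool[:n_shared])
        for n in p:
            # nodes on several paths (convergence hubs) keep every core
            cores[n] = cores.get(n, set()) | core
    for n, core in cores.items():
        own = [t for t in ann[n] if t not in core]
        rng.shuffle(own)
        ann[n] = core | set(own[: max(0, terms_per_node - len(core))])
    return ann


def _calibrate_missing(values: np.ndarray, rate: float, rng) -> np.ndarray:
    """Left-censored-like missingness mask with overall mean `rate`."""
    z = (values - np.nanmean(values)) / (np.nanstd(values) + 1e-12)

    def mean_rate(a):
        return float(np.mean(expit(a - z))) - rate

    a = brentq(mean_rate, -30.0, 30.0)
    return rng.uniform(size=values.shape) < expit(a - z)


def simulate_omics(
    truth: PlantedTruth,
    replicates: int = 3,
    effect_size: float = 2.0,
    noise_sd: float = 0.5,
    missing_rate: float = 0.1,
    seed: int = 0,
    bio_sd: float = 0.35,
):
    """Three coupled omics views over the 2 genotype x 4 treatment grid.

    Factor 1 loads on all drug-treated samples, factor 2 only on the
    combination arm, factor 3 only on the knockout genotype; support
    features carry ``sign * effect_size`` shifts.  mRNA counts are
    gamma-Poisson (negative binomial) around ``2**(base + signal)``;
    protein log-abundance is Gaussian around a latent per-sample level
    (biological variation ``bio_sd`` shared with the phospho view, plus
    measurement noise ``noise_sd``); each phosphosite tracks its parent
    protein's latent level plus site-specific signal.  If regulons are
    attached
    to the truth, targets of planted-active TFs shift by
    ``sign(weight) * activity * effect_size`` in knockout samples.
    Missingness in protein/phospho increases as abundance decreases
    (logistic), with overall mean ``missing_rate``.
    """
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    if replicates < 3:
        raise ValueError("need >= 3 replicates per condition")
    rng = np.random.default_rng(seed)
    nodes = list(getattr(truth, "nodes"))
    site_map = dict(getattr(truth, "site_map"))
    sites = sorted(site_map)

    samples, meta_rows = [], []
    for g in GENOTYPES:
        for t in TREATMENTS:
            for r in range(1, replicates + 1):
                sid = f"{g}_{t}_r{r}"
                samples.append(sid)
                meta_rows.append({"sample_id": sid, "genotype": g, "treatment": t,
                                  "replicate": r, "batch": f"b{r}"})
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    s1 = (meta["treatment"] != "untreated").to_numpy(float)
    s2 = (meta["treatment"] == "combination").to_numpy(float)
    s3 = (meta["genotype"] == "KO").to_numpy(float)
    design = np.column_stack([s1, s2, s3])

    def signal_matrix(view: str, features: list) -> np.ndarray:
        idx = {f: j for j, f in enumerate(features)}
        sig = np.zeros((len(samples), len(features)))
        for k in (1, 2, 3):
            for f, sgn in truth.factor_support.get(k, {}).get(view, {}).items():
                if f in idx:
                    sig[:, idx[f]] += design[:, k - 1] * sgn * effect_size
        if view == "mrna" and truth.regulons:
            for tf, activity in truth.planted_tf_activity.items():
                if activity == 0 or tf not in truth.regulons:
                    continue
                for gene, w in truth.regulons[tf].items():
                    if gene in idx:
                        sig[:, idx[gene]] += s3 * np.sign(w) * activity * effect_size
        return sig

    # mRNA: negative-binomial counts
    base_mrna = rng.uniform(3.0, 9.0, size=len(nodes))
    mu = 2.0 ** (base_mrna[None, :] + signal_matrix("mrna", nodes))
    lam = rng.gamma(shape=1.0 / _NB_DISPERSION, scale=mu * _NB_DISPERSION)
    counts = rng.poisson(lam).astype(np.int64)
    mrna = OmicsView("mrna", pd.DataFrame(counts, index=samples, columns=nodes), meta)

    # protein: latent log2 level (base + signal + biological variation),
    # observed with independent measurement noise
    base_prot = rng.normal(20.0, 2.0, size=len(nodes))
    latent = (base_prot[None, :] + signal_matrix("protein", nodes)
              + rng.normal(0.0, bio_sd, size=(len(samples), len(nodes))))
    prot_vals = latent + rng.normal(0.0, noise_sd,
                                    size=(len(samples), len(nodes)))
    prot_mat = pd.DataFrame(prot_vals, index=samples, columns=nodes)

    # phospho: parent's latent level + site-specific signal + noise
    parent_idx = [nodes.index(site_map[s]) for s in sites]
    ph_vals = (latent[:, parent_idx] + signal_matrix("phospho", sites)
               + rng.normal(0.0, noise_sd, size=(len(samples), len(sites))))
    ph_mat = pd.DataFrame(ph_vals, index=samples, columns=sites)
    ph_feat = pd.DataFrame(
        {"protein": [site_map[s] for s in sites],
         "position": [int(s.rsplit("_", 1)[1][1:]) for s in sites]},
        index=sites,
    )

    if missing_rate > 0:
        prot_mat = prot_mat.mask(_calibrate_missing(prot_mat.to_numpy(), missing_rate, rng))
        ph_mat = ph_mat.mask(_calibrate_missing(ph_mat.to_numpy(), missing_rate, rng))

    protein = OmicsView("protein", prot_mat, meta)
    phospho = OmicsView("phospho", ph_mat, meta, feature_meta=ph_feat)
    return mrna, protein, phospho


def simulate_regulons(truth: PlantedTruth, targets_per_tf: int = 10,
                      seed: int = 0, n_background_tfs: int = 5) -> dict:
    """Signed-weight regulons; planted TFs get nonzero activity, others zero.

    The regulon set is attached to ``truth.regulons`` so that a
    subsequent :func:`simulate_omics` call shifts active-TF targets in
    knockout samples, making TF-activity recovery testable.
    """
    if targets_per_tf < 2:
        raise ValueError("targets_per_tf must be >= 2")
    rng = np.random.default_rng(seed)
    nodes = list(getattr(truth, "nodes"))
    active = sorted(truth.tfs)
    pool = [n for n in nodes if n not in truth.tfs]
    rng.shuffle(pool)
    background = pool[:n_background_tfs]
    regulons: dict = {}
    # exclude genotype-factor support genes (background TFs must stay
    # null under the knockout contrast) and planted pathway members
    # (receptor DE must not be confounded by TF-target shifts);
    # target sets are disjoint across TFs
    geno_support = set(truth.factor_support.get(3, {}).get("mrna", {}))
    reserved = (geno_support | truth.receptors | truth.path_nodes()
                | set(background) | truth.tfs)
    candidates = [n for n in nodes if n not in reserved]
    order = list(rng.permutation(candidates))
    n_fit = len(order) // targets_per_tf
    if n_fit < len(active):
        raise ValueError("not enough genes for disjoint regulons")
    background = background[: max(0, n_fit - len(active))]
    tf_list = active + background
    for i, tf in enumerate(tf_list):
        targets = order[i * targets_per_tf:(i + 1) * targets_per_tf]
        regulons[tf] = {
            g: float(rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.5)) for g in targets
        }
    for tf in background:
        truth.planted_tf_activity.setdefault(tf, 0.0)
    truth.regulons = regulons
    return regulons


def simulate_kinomics(truth: PlantedTruth, seed: int = 0,
                      n_background: int = 20) -> pd.DataFrame:
    """Peptide-array style median kinase activity changes per contrast.

    Planted responsive kinases exceed the |change| > 1 filter;
    background kinases are N(0, 0.3) and essentially never do.
    """
    if not truth.kinases:
        raise ValueError("truth has no planted kinases")
    rng = np.random.default_rng(seed)
    nodes = list(getattr(truth, "nodes"))
    bg_pool = [n for n in nodes if n not in truth.kinases]
    rng.shuffle(bg_pool)
    rows = []
    for contrast in ("combination_vs_untreated", "KO_vs_WT"):
        for k in sorted(truth.kinases):
            change = float(rng.choice([-1.0, 1.0]) * rng.uniform(1.5, 3.0))
            rows.append({"kinase": k, "contrast": contrast,
                         "median_activity_change": change})
        for k in bg_pool[:n_background]:
            rows.append({"kinase": k, "contrast": contrast,
                         "median_activity_change": float(rng.normal(0.0, 0.3))})
    return pd.DataFrame(rows)


def simulate_viability(seed: int = 0, spike_rate: float = 0.0,
                       replicates: int = 4) -> ViabilityTrace:
    """96-h fluorescence viability traces sampled every 4 h (25 points).

    Drug-treated wells decline logistically (knockout slower than WT,
    the resistance phenotype; receptor-targeting gRNA restores the WT
    decline in knockouts); vehicle wells grow.  ``spike_rate`` injects
    multiplicative single-timepoint artifacts for smoothing tests.
    """
    if not (0.0 <= spike_rate <= 0.2):
        raise ValueError("spike_rate must be in [0, 0.2]")
    rng = np.random.default_rng(seed)
    t = np.arange(0, 97, 4, dtype=float)
    rows, meta_rows = [], []
    for g in GENOTYPES:
        for grna in ("empty", "gEGFR"):
            for drug in ("DMSO", "drug"):
                for r in range(1, replicates + 1):
                    well = f"{g}_{grna}_{drug}_r{r}"
                    if drug == "DMSO":
                        trace = 1.0 + 2.0 / (1.0 + np.exp(-(t - 48.0) / 12.0))
                    else:
                        resistant = g == "KO" and grna == "empty"
                        half, floor = (72.0, 0.5) if resistant else (36.0, 0.15)
                        trace = floor + (1.0 - floor) / (1.0 + np.exp((t - half) / 8.0))
                    trace = trace * (1.0 + rng.normal(0.0, 0.02, size=t.size))
                    if spike_rate > 0:
                        spikes = rng.uniform(size=t.size) < spike_rate
                        trace = np.where(spikes, trace * rng.uniform(5.0, 10.0), trace)
                    rows.append(pd.Series(np.abs(trace), index=t, name=well))
                    meta_rows.append({"well": well, "genotype": g, "gRNA": grna,
                                      "drug": drug, "replicate": r})
    matrix = pd.DataFrame(rows)
    well_meta = pd.DataFrame(meta_rows).set_index("well")
    return ViabilityTrace(timepoints=list(t), matrix=matrix, well_meta=well_meta)
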