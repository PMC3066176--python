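"""Residue encoding, SVM training and protein-level cross-validation.

Each residue is represented by a 130-dimensional vector laid out in fixed
blocks:

======================  =====  =========================================
block                   width  contents
======================  =====  =========================================
conservation                1  Shannon entropy of the profile column
identity                   20  residue one-hot (alphabetical one-letter)
aatype                      2  charged (0,0) / polar (0,1) / hydrophobic (1,0)
physchem                    3  polarity, hydrophobicity, volume
accessibility               2  ASA, relative ASA
secondary structure         7  one-hot over H,G,I,E,B,T,S (coil = zeros)
pssm                       20  PSI-BLAST log-odds
freq                       20  weighted observed frequencies
network                     8  degree .. closeness (contact network)
dnsc                        5  signal intensity from each keyAA
layered environment        42  3 layers x 14 averaged features
======================  =====  =========================================

The classifier is an SVM trained on a class-balanced sample (1:1 by
default) with features scaled to [-1, 1] on the training folds only;
cross-validation splits at the protein level so no protein contributes
residues to both sides of a fold.  Feature relevance is ranked by the
squared weights of a linear SVM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_curve, roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from catres.config import Config, DEFAULT_CONFIG
from catres.contact_network import ContactNetwork, build_network, shortest_paths
from catres.centrality import CENTRALITY_NAMES, centrality_table
from catres.dnsc import KeyAASet, dnsc_matrix, select_keyaas
from catres.layered_env import (LAYER_FEATURES, layer_feature_names,
                                layer_features, layer_partition)
from catres.profile_features import (AA_ALPHABET, SS_CODES, ProfileMatrix,
                                     aa_identity, aa_type,
                                     match_dssp, physchem, relative_asa,
                                     shrake_rupley_asa, ss_onehot)
from catres.structure_io import Structure

logger = logging.getLogger(__name__)

# --- feature-name layout ------------------------------------------------

FEATURE_BLOCKS: list[tuple[str, list[str]]] = [
    ("conservation", ["conservation"]),
    ("identity", [f"identity_{aa}" for aa in AA_ALPHABET]),
    ("aatype", ["aatype_1", "aatype_2"]),
    ("physchem", ["polarity", "hydrophobicity", "volume"]),
    ("accessibility", ["asa", "rasa"]),
    ("ss", [f"ss_{c}" for c in SS_CODES]),
    ("pssm", [f"pssm_{aa}" for aa in AA_ALPHABET]),
    ("freq", [f"freq_{aa}" for aa in AA_ALPHABET]),
    ("network", list(CENTRALITY_NAMES)),
    ("dnsc", [f"dnsc_{m}" for m in range(1, 6)]),
    ("layered", layer_feature_names(3)),
]

FEATURE_NAMES: list[str] = [name for _, names in FEATURE_BLOCKS
                            for name in names]
assert len(FEATURE_NAMES) == 130


def block_columns(block: str) -> list[str]:
    """Column names of one encoding block (e.g. ``"dnsc"``)."""
    for name, cols in FEATURE_BLOCKS:
        if name == block:
            return list(cols)
    raise KeyError(f"unknown feature block {block!r}")


# --- dataset containers -------------------------------------------------

@dataclass
class EncodedDataset:
    """Encoded residues: features, labels and protein grouping."""

    X: pd.DataFrame                  # n_residues x 130
    y: np.ndarray                    # 1 = catalytic
    protein_ids: np.ndarray          # one id per row
    residue_keys: list[Hashable]

    def __post_init__(self) -> None:
        n = len(self.X)
        if not (len(self.y) == len(self.protein_ids)
                == len(self.residue_keys) == n):
            raise ValueError("inconsistent dataset lengths")

    @property
    def n_proteins(self) -> int:
        return len(np.unique(self.protein_ids))

    def subset(self, row_mask: np.ndarray) -> "EncodedDataset":
        idx = np.flatnonzero(row_mask) if row_mask.dtype == bool else row_mask
        return EncodedDataset(
            X=self.X.iloc[idx].reset_index(drop=True),
            y=self.y[idx],
            protein_ids=self.protein_ids[idx],
            residue_keys=[self.residue_keys[i] for i in idx],
        )


# --- encoding -----------------------------------------------------------

def encode_chain(structure: Structure, chain_id: str,
                 profile: ProfileMatrix | None = None,
                 dssp: Mapping | None = None,
                 network: ContactNetwork | None = None,
                 config: Config = DEFAULT_CONFIG) -> pd.DataFrame:
    """Encode every residue of one chain as a 130-dim feature row.

    Missing profile -> conservation/PSSM/frequency blocks zero-filled;
    missing DSSP -> internal Shrake–Rupley ASA and all-coil secondary
    structure.  Nonstandard residues are skipped with a warning.
    """
    residues = [r for r in structure.chain(chain_id)]
    standard = [r for r in residues if r.is_standard]
    skipped = len(residues) - len(standard)
    if skipped:
        logger.warning("%d nonstandard residue(s) skipped in %s/%s",
                       skipped, structure.pdb_id, chain_id)

    if network is None:
        network = build_network(structure, chain_id,
                                extra=config.contact_extra,
                                radii=config.vdw_radii,
                                default_radius=config.default_vdw_radius)
    ctable = centrality_table(network)
    keyaas = select_keyaas(network, dict(zip(ctable.index,
                                             ctable["closeness"])),
                           k=config.n_keyaas)
    dnsc = dnsc_matrix(network, keyaas, a=config.dnsc_exponent,
                       g_s=config.dnsc_source_intensity,
                       cutoff=config.dnsc_cutoff)
    dnsc_of = {v: dnsc[i] for i, v in enumerate(network.vertices)}

    # accessibility and secondary structure
    if dssp is not None:
        matched = match_dssp(structure, chain_id, dssp)
        asa_of = {k: (0.0 if np.isnan(a) else float(a))
                  for k, a in matched["asa"].items()}
        ss_of = dict(matched["ss"])
    else:
        asa_of = shrake_rupley_asa(structure, chain_id,
                                   probe=config.asa_probe_radius,
                                   n_points=config.asa_n_points,
                                   radii=config.vdw_radii,
                                   default_radius=config.default_vdw_radius)
        ss_of = {r.key: "coil" for r in residues}

    # profile blocks, matched to chain positions by order
    n = len(residues)
    if profile is not None and profile.n_positions != n:
        logger.warning("profile length %d != chain length %d for %s/%s; "
                       "profile ignored", profile.n_positions, n,
                       structure.pdb_id, chain_id)
        profile = None
    if profile is not None:
        cons = profile.conservation()
        pssm_rows = profile.logodds
        freq_rows = profile.freqs
    else:
        cons = np.zeros(n)
        pssm_rows = np.zeros((n, 20))
        freq_rows = np.zeros((n, 20))

    # per-residue table of the 14 layer-averaged features
    prop_rows = []
    for i, res in enumerate(residues):
        if res.is_standard:
            pol, hyd, vol = physchem(res.name)
            rasa = relative_asa(asa_of[res.key], res.name)
        else:
            pol = hyd = vol = rasa = 0.0
        cent = ctable.loc[[res.key]].iloc[0]
        prop_rows.append([cons[i], pol, hyd, vol, asa_of[res.key], rasa]
                         + [float(cent[c]) for c in CENTRALITY_NAMES])
    properties = pd.DataFrame(
        prop_rows, columns=LAYER_FEATURES,
        index=pd.Index([r.key for r in residues], tupleize_cols=False))

    rows, keys = [], []
    for i, res in enumerate(residues):
        if not res.is_standard:
            continue
        part = layer_partition(network, res.key, depth=config.layer_depth)
        layered, _flags = layer_features(part, properties)
        row = np.concatenate([
            [cons[i]],
            aa_identity(res.name),
            aa_type(res.name),
            physchem(res.name),
            [asa_of[res.key], relative_asa(asa_of[res.key], res.name)],
            ss_onehot(ss_of[res.key]),
            pssm_rows[i],
            freq_rows[i],
            properties.loc[[res.key], CENTRALITY_NAMES].to_numpy()[0],
            dnsc_of[res.key],
        ])
        row = np.concatenate([row, layered])
        if len(row) != 130:
            raise ValueError(f"encoding width {len(row)} != 130")
        rows.append(row)
        keys.append(res.key)

    out = pd.DataFrame(rows, columns=FEATURE_NAMES)
    out.index = pd.Index(keys, tupleize_cols=False)
    return out


def encode_dataset(structures: Mapping[str, Structure],
                   annotations: pd.DataFrame,
                   profiles: Mapping[str, ProfileMatrix] | None = None,
                   networks: Mapping[str, ContactNetwork] | None = None,
                   chain_id: str = "A",
                   config: Config = DEFAULT_CONFIG) -> EncodedDataset:
    """Encode a collection of single-chain structures into one dataset.

    A residue is labeled catalytic when (pdb_id, chain, resnum) appears
    with label ``catalytic`` in the annotation table.
    """
    profiles = profiles or {}
    networks = networks or {}
    frames, labels, prot_ids, keys = [], [], [], []
    for pdb_id, structure in structures.items():
        cat = {
            (chain_id, int(r), "")
            for _, row in annotations.iterrows()
            if row["pdb_id"] == pdb_id and row["chain"] == chain_id
            and row["label"] == "catalytic"
            for r in [row["resnum"]]
        }
        X = encode_chain(structure, chain_id,
                         profile=profiles.get(pdb_id),
                         network=networks.get(pdb_id),
                         config=config)
        frames.append(X.reset_index(drop=True))
        for key in X.index:
            labels.append(1 if key in cat else 0)
            prot_ids.append(pdb_id)
            keys.append((pdb_id,) + key)
    return EncodedDataset(
        X=pd.concat(frames, ignore_index=True),
        y=np.asarray(labels, dtype=int),
        protein_ids=np.asarray(prot_ids, dtype=object),
        residue_keys=keys,
    )


# --- sampling and folds -------------------------------------------------

def balance_sample(dataset: EncodedDataset, ratio: float = 1.0,
                   seed: int = 0) -> EncodedDataset:
    """Keep all positives; subsample negatives to ``ratio`` x positives.

    Negatives are drawn without replacement, uniformly, from each
    protein's own pool, so the class balance is enforced per protein.
    """
    if not (dataset.y == 1).any():
        raise ValueError("dataset has no positive (catalytic) residues")
    rng = np.random.default_rng(seed)
    keep = np.flatnonzero(dataset.y == 1).tolist()
    for pid in np.unique(dataset.protein_ids):
        in_prot = dataset.protein_ids == pid
        n_pos = int((dataset.y[in_prot] == 1).sum())
        neg_idx = np.flatnonzero(in_prot & (dataset.y == 0))
        n_take = min(len(neg_idx), int(round(ratio * n_pos)))
        if n_take:
            keep.extend(rng.choice(neg_idx, size=n_take,
                                   replace=False).tolist())
    keep = np.array(sorted(keep))
    return dataset.subset(keep)


def protein_level_folds(dataset: EncodedDataset, k: int = 10,
                        seed: int = 0) -> dict[str, int]:
    """Partition proteins (not residues) into k folds of near-equal size."""
    proteins = np.unique(dataset.protein_ids)
    if len(proteins) < k:
        raise ValueError(f"{len(proteins)} proteins < {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(proteins)
    return {pid: i % k for i, pid in enumerate(order)}


# --- model --------------------------------------------------------------

@dataclass
class FittedModel:
    """SVM plus the train-set [-1, 1] scaler and the feature layout."""

    scaler: MinMaxScaler
    svc: SVC
    feature_names: list[str]

    def decision_values(self, X: pd.DataFrame) -> np.ndarray:
        return self.svc.decision_function(
            self.scaler.transform(X[self.feature_names]))

    def predict(self, X: pd.DataFrame, threshold: float = 0.0) -> np.ndarray:
        return (self.decision_values(X) >= threshold).astype(int)


#: coarse LIBSVM-style hyperparameter grid used when tuning is requested
DEFAULT_PARAM_GRID = {
    "C": [2.0 ** e for e in (-5, 0, 5, 10, 15)],
    "gamma": [2.0 ** e for e in (-15, -10, -5, 0, 3)],
}


def train_svm(X: pd.DataFrame, y: np.ndarray, kernel: str = "rbf",
              C: float = 8.0, gamma: float | str = "scale",
              feature_subset: Sequence[str] | None = None,
              tune: bool = False,
              param_grid: dict | None = None) -> FittedModel:
    """Fit an SVM on [-1, 1]-scaled features.

    With ``tune=True`` the (C, gamma) pair is chosen by 3-fold grid search
    on the training data; otherwise the given values are used directly.
    """
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    names = list(feature_subset) if feature_subset is not None \
        else list(X.columns)
    scaler = MinMaxScaler(feature_range=(-1.0, 1.0), clip=False)
    Xs = scaler.fit_transform(X[names])
    if tune:
        grid = param_grid or DEFAULT_PARAM_GRID
        search = GridSearchCV(SVC(kernel=kernel), grid, cv=3,
                              scoring="roc_auc", n_jobs=1)
        search.fit(Xs, y)
        svc = search.best_estimator_
    else:
        svc = SVC(kernel=kernel, C=C, gamma=gamma)
        svc.fit(Xs, y)
    return FittedModel(scaler=scaler, svc=svc, feature_names=names)


# --- metrics ------------------------------------------------------------

def evaluate(labels: np.ndarray, decision_values: np.ndarray,
             threshold: float = 0.0) -> dict[str, float]:
    """Confusion metrics (percent) at a decision threshold, plus AUC.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    precision = TP/(TP+FP), accuracy = (TP+TN)/n — all in percent;
    ``auc`` is the rank-statistic ROC area in [0, 1].
    """
    labels = np.asarray(labels)
    scores = np.asarray(decision_values)
    if len(labels) != len(scores):
        raise ValueError("labels and decision values differ in length")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    pct = lambda num, den: 100.0 * num / den if den else float("nan")
    return {
        "sensitivity": pct(tp, tp + fn),
        "specificity": pct(tn, tn + fp),
        "accuracy": pct(tp + tn, len(labels)),
        "precision": pct(tp, tp + fp),
        "auc": float(roc_auc_score(labels, scores)),
    }


def recall_at_precision(labels: np.ndarray, decision_values: np.ndarray,
                        precision_pct: float) -> float:
    """Largest recall (percent) with precision >= ``precision_pct``.

    Swept over all decision-value thresholds; NaN when no threshold
    reaches the requested precision.
    """
    prec, rec, _ = precision_recall_curve(labels, decision_values)
    ok = prec >= precision_pct / 100.0
    if not ok.any():
        return float("nan")
    return float(100.0 * rec[ok].max())


# --- cross-validation ---------------------------------------------------

@dataclass
class CVReport:
    """Per-fold and mean metrics of a protein-level cross-validation."""

    per_fold: pd.DataFrame          # one row per fold, metric columns
    mean: dict[str, float]
    fold_of_protein: dict[str, int]
    roc_points: tuple[np.ndarray, np.ndarray]  # pooled test (fpr, tpr)
    seed: int


def cross_validate(dataset: EncodedDataset, k: int = 10, ratio: float = 1.0,
                   seed: int = 0, kernel: str = "rbf", C: float = 8.0,
                   gamma: float | str = "scale",
                   feature_subset: Sequence[str] | None = None,
                   tune: bool = False) -> CVReport:
    """Protein-level k-fold cross-validation of the residue classifier.

    Training folds are re-balanced (1:1 by default) with a per-fold seeded
    draw; test folds are left unbalanced so precision-style metrics retain
    their natural class skew.  Scaling is fit on the training fold only.
    """
    folds = protein_level_folds(dataset, k=k, seed=seed)
    fold_of_row = np.array([folds[p] for p in dataset.protein_ids])
    records = []
    pooled_labels, pooled_scores = [], []
    for fold in range(k):
        train = dataset.subset(fold_of_row != fold)
        test = dataset.subset(fold_of_row == fold)
        train = balance_sample(train, ratio=ratio,
                               seed=int(np.random.default_rng(
                                   [seed, fold]).integers(2 ** 31)))
        model = train_svm(train.X, train.y, kernel=kernel, C=C, gamma=gamma,
                          feature_subset=feature_subset, tune=tune)
        scores = model.decision_values(test.X)
        metrics = evaluate(test.y, scores)
        metrics["fold"] = fold
        records.append(metrics)
        pooled_labels.append(test.y)
        pooled_scores.append(scores)
    per_fold = pd.DataFrame.from_records(records).set_index("fold")
    mean = {m: float(per_fold[m].mean()) for m in per_fold.columns}
    fpr, tpr, _ = roc_curve(np.concatenate(pooled_labels),
                            np.concatenate(pooled_scores))
    return CVReport(per_fold=per_fold, mean=mean, fold_of_protein=folds,
                    roc_points=(fpr, tpr), seed=seed)


# --- feature ranking ----------------------------------------------------

def rank_features(X: pd.DataFrame, y: np.ndarray,
                  C: float = 1.0) -> pd.DataFrame:
    """Rank features by squared linear-SVM weight, descending.

    Fits a linear-kernel SVM on [-1, 1]-scaled data; ties break by feature
    index so the ranking is deterministic.  Returns a DataFrame with
    columns (feature, weight, weight_sq) ordered by rank.
    """
    model = train_svm(X, y, kernel="linear", C=C)
    w = model.svc.coef_[0]
    order = sorted(range(len(w)), key=lambda i: (-w[i] ** 2, i))
    return pd.DataFrame({
        "feature": [model.feature_names[i] for i in order],
        "weight": [float(w[i]) for i in order],
        "weight_sq": [float(w[i] ** 2) for i in order],
    })


def select_top_features(ranking: pd.DataFrame, n: int) -> list[str]:
    """The ``n`` top-ranked feature names, in rank order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(ranking):
        raise ValueError(f"n={n} exceeds {len(ranking)} ranked features")
    return ranking["feature"].head(n).tolist()


# --- shortest-path distribution analyses --------------------------------

PATH_BINS = ["0", "1", "2", "3", "4", "5", ">5"]


def _bin_of(d: float) -> str:
    if np.isinf(d) or d > 5:
        return ">5"
    return str(int(d))


def path_distribution(networks: Mapping[str, ContactNetwork],
                      keyaas: Mapping[str, KeyAASet],
                      catalytic: Mapping[str, set]) -> pd.DataFrame:
    """Shortest-path histograms between keyAAs and residue classes.

    Rows: ``catalytic`` and ``noncatalytic`` (pooled over all residue ×
    keyAA pairs), ``catalytic_rank{m}`` per keyAA rank, and
    ``catalytic_pairs`` (pairwise among catalytic residues).  Each row is
    a normalized frequency over the distance bins 0,1,...,5,>5.
    """
    counts: dict[str, dict[str, int]] = {}

    def tally(row: str, d: float) -> None:
        counts.setdefault(row, {b: 0 for b in PATH_BINS})[_bin_of(d)] += 1

    any_labels = False
    for pid, network in networks.items():
        cat = catalytic.get(pid, set())
        ks = keyaas[pid]
        dist_from_key = {v: shortest_paths(network, v)
                         for v in ks.vertices}
        for v in network.vertices:
            row = "catalytic" if v in cat else "noncatalytic"
            if v in cat:
                any_labels = True
            for m, key in enumerate(ks.vertices, start=1):
                d = dist_from_key[key][v]
                tally(row, d)
                if v in cat:
                    tally(f"catalytic_rank{m}", d)
        cat_list = sorted(cat, key=network.index_of)
        for i, u in enumerate(cat_list):
            du = shortest_paths(network, u)
            for v in cat_list[i + 1:]:
                tally("catalytic_pairs", du[v])
    if not any_labels:
        raise ValueError("no labeled catalytic residues in any network")
    table = pd.DataFrame.from_dict(counts, orient="index")[PATH_BINS]
    return table.div(table.sum(axis=1), axis=0)


# --- worked-example helper ----------------------------------------------

def keyaa_context(structure: Structure, chain_id: str, resnum: int,
                  icode: str = "", config: Config = DEFAULT_CONFIG
                  ) -> dict:
    """KeyAAs of a chain and the hop distance from one residue to each.

    Returns ``{"keyaas": [labels...], "distances": {label: hops},
    "contacts": {label: bool}}`` for inspecting how a residue of interest
    sits relative to the chain's most central residues.
    """
    network = build_network(structure, chain_id, extra=config.contact_extra,
                            radii=config.vdw_radii,
                            default_radius=config.default_vdw_radius)
    keyaas = select_keyaas(network, k=config.n_keyaas)
    target = (chain_id, resnum, icode)
    if target not in network.graph:
        raise KeyError(f"residue {resnum}{icode} not in chain {chain_id}")
    dist = shortest_paths(network, target)
    label_of = {r.key: r.label for r in structure.chain(chain_id)}
    return {
        "keyaas": [label_of[v] for v in keyaas.vertices],
        "distances": {label_of[v]: dist[v] for v in keyaas.vertices},
        "contacts": {label_of[v]: dist[v] == 1.0 for v in keyaas.vertices},
    }
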