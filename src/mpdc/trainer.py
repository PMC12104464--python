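"""Semi-supervised training loop.

Each iteration assembles a batch with the labeled items first, augments
it (flips and 90-degree rotations applied identically to image and
label), runs the three-branch forward pass, updates the dynamic
threshold from the unlabeled half, decouples pixels into consistent and
inconsistent parts, evaluates all six loss components and takes one SGD
step over every parameter set jointly.

Ablation switches mirror the framework's study axes: branch subsets
(pos+rev / pos+pos+fus / pos+rev+fus), shared vs individual encoders,
dynamic vs fixed threshold, the CPS pair subset, and prediction-map vs
ground-truth inversion in the reverse branch.  Setting
``unsupervised=False`` yields the supervised-only baseline on the same
batch stream (identical labeled data and budget).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import losses as L
from .autodiff import SGD, Tensor
from .data import ImageBatch, PoolSampler, SplitData, batch_from_pairs
from .decoupling import ThresholdState, decouple, split_confidence, update_threshold
from .metrics import evaluate_scans
from .network import MPDCNet, NetworkConfig


_BRANCH_PRESETS = {
    "pos+rev": dict(enabled_branches=("pos", "rev"), reverse_module=True),
    "pos+pos+fus": dict(enabled_branches=("pos", "rev", "fus"), reverse_module=False),
    "pos+rev+fus": dict(enabled_branches=("pos", "rev", "fus"), reverse_module=True),
}


@dataclass
class TrainConfig:
    """Optimisation, batching and ablation settings.

    The reference schedule is SGD (lr 0.01, momentum 0.9, weight decay
    5e-4), batch 24 with 12 labeled, 50 000 iterations; desk-scale runs
    shrink iterations/batch but keep the optimiser.  ``threshold`` is
    "dynamic" or a fixed float; ``branches`` selects the ablation preset;
    ``inversion`` chooses prediction-map or ground-truth inversion for
    the reverse branch's supervised loss.
    """

    iterations: int = 50_000
    lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 5e-4
    lr_schedule: str = "constant"        # "constant" | "poly"
    batch_size: int = 24
    labeled_per_batch: int = 12
    augment: bool = True
    seed: int = 0
    val_interval: int = 200
    inference_head: str = "pos"
    unsupervised: bool = True
    branches: str = "pos+rev+fus"
    shared_encoder: bool = False
    threshold: str | float = "dynamic"
    cps_pairs: tuple[str, ...] = ("P-R", "P-F", "R-F")
    inversion: str = "prediction_map"     # | "ground_truth"
    loss_weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    feat_reduction: str = "mean"
    threshold_source: str = "unlabeled"   # | "all"
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self):
        if self.iterations < 1 or self.lr <= 0 or self.labeled_per_batch < 1:
            raise ValueError("invalid training configuration")
        if self.branches not in _BRANCH_PRESETS:
            raise ValueError(f"unknown branch preset {self.branches!r}")
        if self.inversion not in ("prediction_map", "ground_truth"):
            raise ValueError("inversion must be 'prediction_map' or 'ground_truth'")

    def build_network_config(self) -> NetworkConfig:
        preset = _BRANCH_PRESETS[self.branches]
        base = asdict(self.network)
        base.update(share_encoders=self.shared_encoder, **preset)
        return NetworkConfig(**base)


def augment_batch(batch: ImageBatch, rng: np.random.Generator) -> ImageBatch:
    """Random H/V flips (p=0.5 each) and 90-degree rotations per item.

    The identical transform is applied to the image and, for labeled
    items, the label map (nearest semantics: pure array reorientation).
    """
    images = batch.images.copy()
    labels = batch.labels.copy()
    for i in range(images.shape[0]):
        flip_h = rng.random() < 0.5
        flip_v = rng.random() < 0.5
        k = int(rng.integers(0, 4))

        def tf(arr):
            if flip_h:
                arr = arr[..., ::-1]
            if flip_v:
                arr = arr[..., ::-1, :]
            return np.rot90(arr, k, axes=(-2, -1))

        images[i] = tf(images[i])
        if i < batch.labeled_count:
            labels[i] = tf(labels[i])
    return ImageBatch(images=np.ascontiguousarray(images),
                      labels=np.ascontiguousarray(labels),
                      labeled_count=batch.labeled_count, metadata=batch.metadata)


@dataclass
class StepDiagnostics:
    gamma: float
    m_confidence: float
    consistent_fraction: float
    cps_terms: int


def train_step(net: MPDCNet, batch: ImageBatch, state: ThresholdState,
               config: TrainConfig, optimizer: SGD
               ) -> tuple[L.LossBundle, ThresholdState, StepDiagnostics]:
    """One optimisation step; returns losses, new threshold state, diagnostics."""
    net.train()
    outputs = net.forward(batch.images)
    lc = batch.labeled_count
    sup_p, sup_r, sup_f = L.supervised_losses(
        outputs, batch.labels, lc, gt_inversion=(config.inversion == "ground_truth"))

    zero = Tensor(np.float32(0.0))
    cps = dc = feat = zero
    gamma = state.gamma
    m_conf = 0.0
    con_frac = 0.0
    n_terms = 0
    if config.unsupervised:
        src = slice(lc, None) if config.threshold_source == "unlabeled" else slice(None)
        p_pos_u, p_rev_u = outputs.P_pos[src], outputs.P_rev[src]
        if p_pos_u.shape[0] > 0:
            if config.threshold == "dynamic":
                if state.iteration < state.i_max:
                    state = update_threshold(state, p_pos_u, p_rev_u)
                gamma = state.gamma
            else:
                gamma = float(config.threshold)
            masks = decouple(p_pos_u, p_rev_u, gamma)
            h_pos, l_pos, h_rev, l_rev = split_confidence(p_pos_u, p_rev_u, masks)
            dc = L.direction_consistency_loss(h_pos, l_pos, h_rev, l_rev, masks)
            m_conf = L.mean_confidence(p_pos_u, p_rev_u)
            cps, n_terms = cps_with_slice(outputs, masks, m_conf, src, config.cps_pairs)
            con_frac = float(masks.consistent.mean())
        feat = feature_losses(outputs, config.feat_reduction)

    total, bundle = L.total_loss(sup_p, sup_r, sup_f, cps, dc, feat,
                                 weights=config.loss_weights)
    optimizer.zero_grad()
    total.backward()
    optimizer.step()
    return bundle, state, StepDiagnostics(gamma=gamma, m_confidence=m_conf,
                                          consistent_fraction=con_frac,
                                          cps_terms=n_terms)


def cps_with_slice(outputs, masks, m_conf, src, pairs):
    return L.cps_loss(outputs, masks, m_conf, batch_slice=src, pairs=pairs)


def feature_losses(outputs, reduction: str) -> Tensor:
    """Encoder/decoder feature consistency, positive + reverse branch."""
    feat = L.feature_consistency_loss(outputs.enc_pyramids["pos"],
                                      outputs.dec_pyramids["pos"], reduction=reduction)
    feat = feat + L.feature_consistency_loss(outputs.enc_pyramids["rev"],
                                             outputs.dec_pyramids["rev"], reduction=reduction)
    return feat


# ---------------------------------------------------------------------------
# full training runs
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    net: MPDCNet
    log: list[dict]
    best_state: dict
    best_val_dice: float
    threshold_state: ThresholdState

    def log_column(self, key: str) -> np.ndarray:
        return np.array([row[key] for row in self.log], dtype=float)


def evaluate_split(net: MPDCNet, pairs, n_classes: int, head: str = "pos") -> dict[str, float]:
    """Mean metrics over the scans of a labeled split (2-D slices re-stacked)."""
    by_scan_pred: dict[str, list] = {}
    by_scan_true: dict[str, list] = {}
    groups: dict[str, list] = {}
    for p in pairs:
        groups.setdefault(p.scan_id, []).append(p)
    for scan_id, items in groups.items():
        items.sort(key=lambda p: p.slice_index)
        images = np.stack([it.image for it in items])[:, None].astype(np.float32)
        preds = net.predict(images, head=head)
        by_scan_pred[scan_id] = preds
        by_scan_true[scan_id] = np.stack([it.label for it in items])
    report = evaluate_scans(by_scan_pred, by_scan_true, n_classes)
    return report.aggregate()


def fit(config: TrainConfig, data: SplitData, out_dir: str | Path | None = None,
        log_every: int = 10) -> TrainResult:
    """Run ``config.iterations`` training steps on ``data``.

    Keeps the best-validation-Dice parameter state (positive head) and
    writes a CSV log plus the resolved configuration when ``out_dir`` is
    given.
    """
    net_cfg = config.build_network_config()
    net = MPDCNet(net_cfg, rng_seed=config.seed)
    optimizer = SGD(net.parameters(), lr=config.lr, momentum=config.momentum,
                    weight_decay=config.weight_decay)
    state = ThresholdState.initial(net_cfg.n_classes, config.iterations)
    rng = np.random.default_rng(config.seed)
    sampler_l = PoolSampler(data.labeled, rng)
    sampler_u = PoolSampler(data.unlabeled, rng) if data.unlabeled else None

    log: list[dict] = []
    best_val, best_state = -1.0, net.state_dict()
    n_unlab = config.batch_size - config.labeled_per_batch
    for it in range(config.iterations):
        if config.lr_schedule == "poly":
            optimizer.lr = config.lr * (1 - it / config.iterations) ** 0.9
        picks = sampler_l.draw(config.labeled_per_batch)
        if n_unlab and sampler_u is not None:
            picks = picks + sampler_u.draw(n_unlab)
        batch = batch_from_pairs(picks, config.labeled_per_batch)
        if config.augment:
            batch = augment_batch(batch, rng)
        bundle, state, diag = train_step(net, batch, state, config, optimizer)

        row = {"step": it, **bundle.as_dict(), "gamma": diag.gamma,
               "m": diag.m_confidence, "con_frac": diag.consistent_fraction,
               "val_dice": np.nan}
        if data.val and ((it + 1) % config.val_interval == 0 or it + 1 == config.iterations):
            val = evaluate_split(net, data.val, net_cfg.n_classes, head=config.inference_head)
            row["val_dice"] = val["dice"]
            if val["dice"] >= best_val:
                best_val, best_state = val["dice"], net.state_dict()
        if it % log_every == 0 or not np.isnan(row["val_dice"]):
            log.append(row)

    if best_val < 0:
        best_state, best_val = net.state_dict(), float("nan")
    result = TrainResult(net=net, log=log, best_state=best_state,
                         best_val_dice=best_val, threshold_state=state)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_log_csv(log, out / "train_log.csv")
        with open(out / "config.json", "w") as f:
            json.dump(config_to_dict(config), f, indent=2)
        save_checkpoint(out / "last.npz", net, optimizer, state, rng)
    return result


def write_log_csv(log: list[dict], path: str | Path) -> None:
    if not log:
        return
    with open(path, "w", newline="") as f:
        writer = csv.DictWriter(f, fieldnames=list(log[0]))
        writer.writeheader()
        writer.writerows(log)


def config_to_dict(config: TrainConfig) -> dict:
    d = asdict(config)
    d["cps_pairs"] = list(config.cps_pairs)
    return d


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, net: MPDCNet, optimizer: SGD,
                    state: ThresholdState, rng: np.random.Generator | None = None) -> None:
    """All five parameter sets + buffers + optimizer momentum + threshold state."""
    payload = {f"net/{k}": v for k, v in net.state_dict().items()}
    for i, v in enumerate(optimizer.state_arrays()):
        payload[f"opt/{i}"] = v
    payload["threshold_json"] = np.frombuffer(
        json.dumps(state.as_dict()).encode(), dtype=np.uint8)
    if rng is not None:
        payload["rng_json"] = np.frombuffer(
            json.dumps(rng.bit_generator.state).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path: str | Path, net: MPDCNet, optimizer: SGD | None = None
                    ) -> tuple[ThresholdState, dict | None]:
    """Restore network (and optionally optimizer) state; returns threshold state
    and the saved RNG state dict (or None)."""
    with np.load(path) as z:
        net.load_state_dict({k[4:]: z[k] for k in z.files if k.startswith("net/")})
        if optimizer is not None:
            arrays = [z[f"opt/{i}"] for i in range(len(optimizer.state_arrays()))]
            optimizer.load_state_arrays(arrays)
        tstate = ThresholdState.from_dict(
            json.loads(bytes(z["threshold_json"]).decode()))
        rng_state = (json.loads(bytes(z["rng_json"]).decode())
                     if "rng_json" in z.files else None)
    return tstate, rng_state
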