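"""Model losses (against straight-line recomputation oracles), the
classical-MIL reduction, Monte-Carlo prediction, and the training loop."""

import numpy as np
import pytest

from conftest import make_small_dae, make_small_vae, random_bag
from vaemil import (
    DeterministicAEAttentionMIL,
    FeatureBag,
    TrainConfig,
    VAEAttentionMIL,
    load_checkpoint,
    simulate_ind_dataset,
    SimulationConfig,
)
from vaemil.attention import attend_pool, attention_scores, classify
from vaemil.variational import LOG_2PI


def _bce(logit, y):
    return np.logaddexp(0.0, logit) - y * logit


def test_vae_loss_matches_straight_line_recomputation():
    """encode -> sample -> decode -> pool -> classify, summed by hand."""
    model = make_small_vae(n_features=4, sizes=(5, 2), attention_dim=3, seed=2)
    rng = np.random.default_rng(7)
    bag = FeatureBag(bag_id="b", features=rng.standard_normal((3, 4)), label=1)
    breakdown = model.loss(bag, S=1, rng=np.random.default_rng(11))

    # independent recomputation with the same standard-normal draw
    X = bag.features.astype(np.float64)
    means, scales = model.autoencoder.encode_np(X)
    D = means.shape[1]
    eps = np.random.default_rng(11).standard_normal((3, D))
    Z = means + scales * eps
    dec_means, dec_vars = model.autoencoder.decode_np(Z)
    recon = 0.0
    for i in range(3):
        v = dec_vars[i, 0]
        recon -= -0.5 * 4 * (LOG_2PI + np.log(v)) - ((X[i] - dec_means[i]) ** 2).sum() / (2 * v)
    kl = 0.0
    for i in range(3):
        s = scales[i, 0]
        kl += 0.5 * ((means[i] ** 2).sum() + D * (s**2 - 1.0 - 2.0 * np.log(s)))
    out = attention_scores(Z, model.attention_params())
    pooled = attend_pool(Z, out.raw_scores)
    logit, _ = classify(pooled.bag_representation, model.classifier_params())
    cls = _bce(logit, 1)

    assert abs(breakdown.classification_term - cls) < 1e-9
    assert abs(breakdown.reconstruction_term - recon) < 1e-8
    assert abs(breakdown.kl_or_latent_term - kl) < 1e-9
    assert abs(breakdown.total - (cls + recon + kl)) < 1e-6


def test_vae_loss_kl_zero_for_prior_posterior():
    """If the encoder outputs the prior's parameters, the KL term vanishes."""
    model = make_small_vae(n_features=4, sizes=(5, 2), attention_dim=3, seed=0)
    p = model.params
    for k in p:
        if k.startswith("enc"):
            p[k] = np.zeros_like(p[k])
    # mean head zero -> mean 0; scale head output softplus(b); solve softplus(b)=1
    p["enc_scale_b"] = np.array([np.log(np.e - 1.0)])  # softplus -> 1.0
    bag = FeatureBag(bag_id="b", features=np.zeros((2, 4)), label=0)
    breakdown = model.loss(bag, S=1, rng=0)
    assert abs(breakdown.kl_or_latent_term) < 1e-9


def test_unlabelled_bag_is_rejected_by_losses():
    bag = FeatureBag(bag_id="ood", features=np.zeros((2, 4)))
    with pytest.raises(ValueError):
        make_small_vae(n_features=4).loss(bag, S=1, rng=0)
    with pytest.raises(ValueError):
        make_small_dae(n_features=4).loss(bag)


def test_dae_loss_reduces_to_classical_mil_at_zero_weights():
    """alpha = beta = 0 must equal the plain attention-MIL NLL exactly."""
    rng = np.random.default_rng(0)
    model = make_small_dae(n_features=6, sizes=(8, 4), attention_dim=5, seed=1)
    for i in range(100):
        bag = random_bag(rng, n_instances=int(rng.integers(1, 15)),
                         label=int(rng.integers(0, 2)), bag_id=f"b{i}")
        breakdown = model.loss(bag, weights=(1.0, 0.0, 0.0))
        Z, _ = model.autoencoder.encode_np(bag.features)
        out = attention_scores(Z, model.attention_params())
        pooled = attend_pool(Z, out.raw_scores)
        logit, _ = classify(pooled.bag_representation, model.classifier_params())
        assert abs(breakdown.total - _bce(logit, bag.label)) < 1e-7


def test_dae_loss_breakdown_totals_and_weights():
    rng = np.random.default_rng(3)
    model = make_small_dae(n_features=6, seed=4)
    bag = random_bag(rng, label=1)
    b = model.loss(bag, weights=(0.7, 0.2, 0.1))
    expected = 0.7 * b.classification_term + 0.2 * b.reconstruction_term + 0.1 * b.kl_or_latent_term
    assert abs(b.total - expected) < 1e-6
    assert b.reconstruction_term >= 0 and b.kl_or_latent_term >= 0
    with pytest.raises(ValueError):
        TrainConfig(alpha=-0.1)


def test_vae_predict_is_mean_of_sigmoids_and_in_unit_interval():
    model = make_small_vae(seed=5)
    rng = np.random.default_rng(0)
    bag = random_bag(rng, n_instances=4, label=1)
    for S in (1, 7):
        p = model.predict_bag(bag, S=S, rng=np.random.default_rng(1))
        assert 0.0 < p < 1.0
    # S Monte Carlo draws averaged by hand
    means, scales = model.autoencoder.encode_np(bag.features)
    r = np.random.default_rng(1)
    probs = []
    for _ in range(7):
        Z = means + scales * r.standard_normal(means.shape)
        logit = model._forward_logit(Z)
        probs.append(1.0 / (1.0 + np.exp(-logit)))
    p7 = model.predict_bag(bag, S=7, rng=np.random.default_rng(1))
    assert abs(p7 - np.mean(probs)) < 1e-12


def test_vae_predict_monte_carlo_converges():
    """S=10^4 estimate within 3 standard errors of the S=10^5 estimate."""
    model = make_small_vae(seed=6)
    bag = random_bag(np.random.default_rng(2), n_instances=3, label=1)
    p_small = model.predict_bag(bag, S=10**4, rng=np.random.default_rng(0))
    p_big = model.predict_bag(bag, S=10**5, rng=np.random.default_rng(1))
    # estimate per-draw std from an independent batch
    means, scales = model.autoencoder.encode_np(bag.features)
    r = np.random.default_rng(2)
    draws = []
    for _ in range(2000):
        Z = means + scales * r.standard_normal(means.shape)
        draws.append(1.0 / (1.0 + np.exp(-model._forward_logit(Z))))
    se = np.std(draws) / np.sqrt(10**4)
    assert abs(p_small - p_big) < 3 * se + 3 * np.std(draws) / np.sqrt(10**5)


def test_degenerate_posterior_prediction_is_deterministic():
    model = make_small_vae(seed=7)
    # force the scale head to the floor
    model.params["enc_scale_W"] = np.zeros_like(model.params["enc_scale_W"])
    model.params["enc_scale_b"] = np.full_like(model.params["enc_scale_b"], -40.0)
    bag = random_bag(np.random.default_rng(3), label=0)
    p1 = model.predict_bag(bag, S=5, rng=np.random.default_rng(0))
    p2 = model.predict_bag(bag, S=1, rng=np.random.default_rng(99))
    pm = model.predict_bag(bag, use_posterior_mean=True)
    assert abs(p1 - p2) < 1e-6 and abs(p1 - pm) < 1e-6


def test_dae_predict_deterministic_and_permutation_invariant():
    model = make_small_dae(seed=8)
    rng = np.random.default_rng(4)
    bag = random_bag(rng, n_instances=9, label=1)
    p1 = model.predict_bag(bag)
    assert p1 == model.predict_bag(bag)
    perm = rng.permutation(9)
    p2 = model.predict_bag(FeatureBag(bag_id="p", features=bag.features[perm], label=1))
    assert abs(p1 - p2) < 1e-6


def test_zero_classifier_outputs_half():
    model = make_small_dae(seed=9)
    model.params["cls_w"] = np.zeros_like(model.params["cls_w"])
    model.params["cls_b"] = np.zeros(())
    bag = random_bag(np.random.default_rng(5), label=1)
    assert abs(model.predict_bag(bag) - 0.5) < 1e-12


def _tiny_train_bags(seed=0, n=16):
    cfg = SimulationConfig(n_bags=n, P=8, latent_rank=3, bag_size_range=(4, 8), seed=seed)
    return simulate_ind_dataset(cfg)


@pytest.mark.parametrize("model_cls", [VAEAttentionMIL, DeterministicAEAttentionMIL])
def test_training_is_reproducible_and_logs_every_epoch(model_cls):
    cfg = TrainConfig(epochs=3, learning_rate=1e-3, seed=42)
    results = []
    for _ in range(2):
        bags = _tiny_train_bags()
        model = model_cls(bags, layer_sizes=(8, 4), attention_dim=4)
        results.append(model.fit(cfg))
    a, b = results
    assert len(a.history) == 3
    assert a.selected_epoch == b.selected_epoch
    assert a.history["train_loss"].iloc[-1] == b.history["train_loss"].iloc[-1]
    np.testing.assert_array_equal(a.history["val_auc"], b.history["val_auc"])


def test_training_rejects_single_class_data():
    bags = [b for b in _tiny_train_bags() if b.label == 0]
    model = DeterministicAEAttentionMIL(bags, layer_sizes=(8, 4), attention_dim=4)
    with pytest.raises(ValueError):
        model.fit(TrainConfig(epochs=1))


def test_checkpoint_round_trip_restores_forward_pass(tmp_path):
    bags = _tiny_train_bags()
    model = VAEAttentionMIL(bags, layer_sizes=(8, 4), attention_dim=4)
    res = model.fit(TrainConfig(epochs=2, seed=3))
    path = tmp_path / "ckpt.npz"
    res.save(path)
    back = load_checkpoint(path)
    test_bag = bags[0]
    p0 = res.model.predict_bag(test_bag, S=3, rng=np.random.default_rng(0))
    p1 = back.model.predict_bag(test_bag, S=3, rng=np.random.default_rng(0))
    assert p0 == p1
    assert back.selected_epoch == res.selected_epoch
    assert back.config.seed == 3


def test_elbo_lower_bounds_importance_sampled_joint_likelihood():
    """Jensen direction: the mean one-sample negative ELBO over many
    seeds is >= the negative log joint likelihood estimated by
    large-S importance sampling."""
    model = make_small_vae(n_features=4, sizes=(5, 2), attention_dim=3, seed=10)
    rng = np.random.default_rng(0)
    bag = FeatureBag(bag_id="b", features=0.5 * rng.standard_normal((3, 4)), label=1)
    neg_elbos = np.array(
        [model.loss(bag, S=1, rng=np.random.default_rng(s)).total for s in range(300)]
    )
    # importance sampling of p(X, y) with S = 10^4 joint posterior draws
    X = bag.features.astype(np.float64)
    means, scales = model.autoencoder.encode_np(X)
    D = means.shape[1]
    r = np.random.default_rng(123)
    S = 10**4
    log_ws = np.empty(S)
    for s in range(S):
        eps = r.standard_normal(means.shape)
        Z = means + scales * eps
        dec_means, dec_vars = model.autoencoder.decode_np(Z)
        ll = (-0.5 * 4 * (LOG_2PI + np.log(dec_vars[:, 0]))
              - ((X - dec_means) ** 2).sum(axis=1) / (2 * dec_vars[:, 0])).sum()
        lp = (-0.5 * D * LOG_2PI - 0.5 * (Z**2).sum(axis=1)).sum()
        lq = (-0.5 * D * (LOG_2PI + 2 * np.log(scales[:, 0]))
              - 0.5 * (eps**2).sum(axis=1) * 1.0).sum()
        logit = model._forward_logit(Z)
        lcls = -_bce(logit, bag.label)
        log_ws[s] = ll + lp - lq + lcls
    from scipy.special import logsumexp

    log_joint = logsumexp(log_ws) - np.log(S)
    se = neg_elbos.std() / np.sqrt(len(neg_elbos))
    assert neg_elbos.mean() >= -log_joint - 3 * se


def test_train_loss_decreases_on_benchmark(benchmark_runs):
    """Mean train loss over the last 5 epochs is below the first 5."""
    for run in benchmark_runs.values():
        for key in ("vae", "dae"):
            tl = run[key].history["train_loss"].to_numpy()
            assert tl[-5:].mean() < tl[:5].mean()
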