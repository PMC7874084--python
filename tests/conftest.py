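import numpy as np
import pytest

import hope


@pytest.fixture(scope="session")
def community4():
    """Default 4-guild, 40-OTU community (seed 3)."""
    return hope.generate_community(hope.SyntheticConfig(seed=3))


@pytest.fixture(scope="session")
def net4(community4):
    corr = hope.sparcc_correlation(community4.abundance)
    return hope.build_network(corr)


@pytest.fixture(scope="session")
def community6():
    """Assortative 6-guild community used by the hypothesis tests."""
    cfg = hope.SyntheticConfig(
        n_guilds=6, otus_per_guild=10, label_noise=0.05, seed=2
    )
    return hope.generate_community(cfg)


@pytest.fixture(scope="session")
def net6(community6):
    corr = hope.sparcc_correlation(community6.abundance)
    return hope.build_network(corr)


@pytest.fixture(scope="session")
def small_trained():
    """A small fitted classifier shared by prediction/serialization tests."""
    syn = hope.SyntheticConfig(
        n_guilds=4, otus_per_guild=10, n_classes=10, seed=5
    )
    com = hope.generate_community(syn)
    net = hope.build_network(hope.sparcc_correlation(com.abundance))
    fm = hope.kmer_frequencies(com.sequences, k=3)
    clf = hope.HopeClassifier(
        net, fm, com.labels, sampler=hope.SamplerConfig([5, 3], 0)
    )
    cfg = hope.TrainConfig(epochs=20, seed=0, embed_dim=16, hidden_dim=16)
    res = clf.fit(net.otu_ids[:30], net.otu_ids[30:], cfg)
    return com, net, fm, clf, res


def random_binary_pair(rng, n=50, c=20, p=0.3):
    pred = (rng.random((n, c)) < p).astype(int)
    truth = (rng.random((n, c)) < p).astype(int)
    return pred, truth
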