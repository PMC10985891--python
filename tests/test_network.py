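"""Architecture contracts: shapes, attention bounds, receptive fields, heads."""

import numpy as np
import pytest

from vessel3.network import (AMFF, ASPPHead, Decoder, Encoder, NetworkConfig,
                             VesselSegNet, build_aspp_head, forward_image,
                             load_weights, save_weights)
from vessel3.nn import Conv2d


SMALL = NetworkConfig(width=16, decode_channels=16, seed=0)


class TestShapes:
    def test_encoder_divide_by_eight(self):
        enc = Encoder(width=16)
        enc.eval()
        x = np.zeros((1, 1, 128, 128), dtype=np.float32)
        assert enc(x).shape == (1, 16, 16, 16)

    def test_encoder_rejects_bad_sizes(self):
        enc = Encoder(width=8)
        with pytest.raises(ValueError):
            enc(np.zeros((1, 1, 100, 100), dtype=np.float32))
        with pytest.raises(ValueError):
            enc(np.zeros((64, 64), dtype=np.float32))

    def test_amff_concatenation_arithmetic(self):
        amff = AMFF(in_ch=16, branch_count=2, dilations=(1, 6))
        amff.eval()
        assert amff(np.zeros((1, 16, 32, 32), np.float32)).shape == (1, 32, 32, 32)

    def test_head_shape_parity(self):
        x = np.random.default_rng(0).normal(size=(1, 16, 16, 16)).astype(np.float32)
        amff = AMFF(in_ch=16).eval()
        aspp = build_aspp_head(in_ch=16).eval()
        assert amff(x).shape == aspp(x).shape == (1, 64, 16, 16)

    def test_forward_shapes_for_both_heads(self):
        for head in ("amff", "aspp"):
            model = VesselSegNet(NetworkConfig(width=16, decode_channels=16,
                                               head=head))
            out = forward_image(model, np.zeros((64, 64)))
            assert out.logits.shape == (1, 3, 64, 64)

    def test_dilation_rates_must_increase(self):
        with pytest.raises(ValueError):
            NetworkConfig(dilations=(1, 6, 6, 18))


class TestBehavior:
    def test_forward_deterministic_in_eval(self):
        model = VesselSegNet(SMALL)
        x = np.random.default_rng(1).normal(size=(1, 1, 64, 64)).astype(np.float32)
        a = model.predict(x).probabilities
        b = model.predict(x).probabilities
        np.testing.assert_array_equal(a, b)

    def test_probabilities_in_unit_interval(self):
        model = VesselSegNet(SMALL)
        rng = np.random.default_rng(2)
        for _ in range(3):
            out = model.predict(rng.normal(size=(1, 1, 64, 64)).astype(np.float32))
            assert out.probabilities.min() >= 0 and out.probabilities.max() <= 1

    def test_masks_threshold_and_tie_break(self):
        from vessel3.network import NetworkOutput
        p = np.zeros((1, 3, 2, 2))
        p[0, :, 0, 0] = [0.9, 0.9, 0.2]      # tie -> lower class index (PA)
        p[0, :, 0, 1] = [0.2, 0.3, 0.8]      # SVC
        p[0, :, 1, 0] = [0.4, 0.4, 0.4]      # below threshold -> background
        m = NetworkOutput(logits=p, probabilities=p).masks(threshold=0.5)
        assert m[0, 0, 0] == 1 and m[0, 0, 1] == 3 and m[0, 1, 0] == 0

    def test_decode_constant_input_gives_constant_interior(self):
        dec = Decoder(in_ch=8, mid_ch=8, up=8)
        dec.eval()
        y = dec(np.full((1, 8, 8, 8), 0.3, dtype=np.float32))
        interior = y[0, :, 24:-24, 24:-24]   # away from conv/upsample borders
        for c in range(3):
            assert np.ptp(interior[c]) < 1e-5

    def test_receptive_field_grows_with_dilation(self):
        # gradient footprint of one output pixel widens as dilation increases
        footprints = {}
        for d in (1, 6):
            conv = Conv2d(1, 1, 3, padding=d, dilation=d,
                          rng=np.random.default_rng(0))
            x = np.zeros((1, 1, 31, 31), dtype=np.float32)
            conv(x)
            g = np.zeros((1, 1, 31, 31), dtype=np.float32)
            g[0, 0, 15, 15] = 1.0
            gin = conv.backward(g)
            rows = np.nonzero(np.abs(gin[0, 0]).sum(axis=1))[0]
            footprints[d] = rows.max() - rows.min()
        assert footprints[6] > footprints[1]
        assert footprints[1] == 2 and footprints[6] == 12


class TestHeads:
    def test_aspp_has_fewer_parameters_than_amff(self):
        amff = AMFF(in_ch=16)
        aspp = build_aspp_head(in_ch=16)
        assert aspp.num_parameters() < amff.num_parameters()

    def test_heads_swap_without_touching_encoder_decoder(self):
        a = VesselSegNet(NetworkConfig(width=16, decode_channels=16, head="amff"))
        b = VesselSegNet(NetworkConfig(width=16, decode_channels=16, head="aspp"))
        a_keys = set(a.state_dict())
        b_keys = set(b.state_dict())
        shared = {k for k in a_keys & b_keys if not k.startswith("head.")}
        assert any(k.startswith("encoder.") for k in shared)
        assert any(k.startswith("decoder.") for k in shared)
        # head namespaces differ only under the "head." prefix
        assert {k for k in a_keys ^ b_keys} <= \
            {k for k in a_keys | b_keys if k.startswith("head.")}

    def test_hierarchical_connection_feeds_next_branch(self):
        # zeroing branch 0's conv changes branch 1's output in AMFF
        rng = np.random.default_rng(3)
        x = rng.normal(size=(1, 8, 12, 12)).astype(np.float32)
        amff = AMFF(in_ch=8, branch_count=2, dilations=(1, 2),
                    rng=np.random.default_rng(1))
        amff.eval()
        before = amff(x)[:, 8:]
        amff.branches[0].conv.weight.data[...] = 0.0
        after = amff(x)[:, 8:]
        assert not np.allclose(before, after)
        # whereas ASPP branches are independent
        aspp = ASPPHead(in_ch=8, branch_count=2, dilations=(1, 2),
                        rng=np.random.default_rng(1))
        aspp.eval()
        before = aspp(x)[:, 8:]
        aspp.branches[0].conv.weight.data[...] = 0.0
        assert np.allclose(before, aspp(x)[:, 8:])


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        a = VesselSegNet(SMALL)
        b = VesselSegNet(NetworkConfig(width=16, decode_channels=16, seed=99))
        path = tmp_path / "weights.npz"
        save_weights(a, path)
        load_weights(b, path)
        x = np.random.default_rng(4).normal(size=(1, 1, 64, 64)).astype(np.float32)
        np.testing.assert_array_equal(a.predict(x).logits, b.predict(x).logits)
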