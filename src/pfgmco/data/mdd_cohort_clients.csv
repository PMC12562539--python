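client_id,site_indices,n_nc,n_mdd
client1,S1;S2;S3;S5;S6;S24,198,191
client2,S7;S8;S9;S10;S11,236,245
client3,S12;S13;S14;S15;S16;S23,166,234
client4,S17;S18;S21;S22;S25,217,273
client5,S20,251,282
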