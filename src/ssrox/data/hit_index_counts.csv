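dataset,dose_kgy,dose_rate_mgy_s,transmission_pct,frame_rate_hz,n_images,n_hits,n_indexed
L21k-1,21,2.1,9.49,100,22200,8977,6715
L21k-2,21,2.1,9.49,100,22200,9581,7371
L42k-1,42,4.2,19.4,100,22200,9617,7696
L42k-2,42,4.2,19.4,100,22200,13657,9548
L83k-1,83,8.3,40.1,100,22200,12783,9240
L83k-2,83,8.3,40.1,100,22200,7987,6557
L210k-1,210,21,94.2,100,22200,9803,5677
L210k-2,210,21,94.2,100,22200,5099,4003
L420k-1,420,23,100,54,22200,12583,7615
L420k-2,420,23,100,54,22200,6404,4591
L830k-1,830,23,100,27,22200,5081,3320
L830k-2,830,23,100,27,22200,15322,6886
L1700k-1,1700,23,100,13,22200,9856,5167
L1700k-2,1700,23,100,13,22200,3471,2691
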