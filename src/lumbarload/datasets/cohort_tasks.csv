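task,mean,mean_sd,peak,peak_sd,variance,variance_sd,rank,rank_sd,borg,borg_sd
light,18.7,8.1,166.4,195.5,13.0,10.6,1.0,0.0,0.9,0.8
static,26.3,19.2,153.5,106.1,13.7,9.9,3.6,1.3,3.8,1.6
heavy_dynamic,30.7,20.0,218.5,154.4,19.8,13.8,4.8,0.4,6.0,2.0
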