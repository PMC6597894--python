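preset_id,delta,n_members,drive_gain,cohesion_gain,center_freq_hz,bandwidth_hz,peak_gain
p00,0.02171852899699367,20,2.322107832496213,2.322107832496213,4.709100967084409,2.505792260895694,2.5741787585291993
p01,0.032352179085775035,20,2.3559074185729503,2.3559074185729503,7.022553749223756,3.7398370483886048,2.5956948432530313
p02,0.04793930536587743,20,2.407467243771715,2.407467243771715,10.472542743391266,5.570214144722583,2.6277102316805507
p03,0.07048223721964275,20,2.4866476587254973,2.4866476587254973,15.617417171677749,8.31241173342219,2.6719528514626374
p04,0.10243166803600434,20,2.6094811438021615,2.6094811438021615,24.65813058036831,12.189217768443154,2.7613481262569968
p05,0.14634934439350367,20,2.8029887252208474,2.8029887252208474,36.771997153254176,17.66185822144324,2.9081817126151956
p06,0.20397031174232716,20,3.115166091894077,3.115166091894077,54.83707575607851,25.22789460761087,3.154461823812507
p07,0.27425046594664204,20,3.638310230407801,3.638310230407801,86.5815236780072,35.38379426641083,3.6089813157288724
p08,0.3499754269777914,20,4.574507803105816,4.574507803105816,129.11666323751518,46.04575053999142,4.716146660785413
p09,0.4119934283717519,20,6.486017681285933,3.056296362061056,192.54815597365803,56.688174906535295,7.86989373589211
p10,0.4133106357766205,20,12.001554146062821,1.6437883487572207,304.0117018592474,56.786348676139596,26.929404760873354
p11,0.18095544689175558,20,108.12310414266697,0.7452442118401476,453.3643537529364,23.10498233637162,3998.375673305713
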