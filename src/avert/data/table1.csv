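name,modality,jurisdiction,country_scope,period_start,period_end,n_events,source_note
National Overdose Response Service (NORS),hotline,Canada,canada,2020-12,2023-04,77,Call log data; emergency medical responses initiated
Digital Overdose Response Service (DORS),app,Alberta,canada,2021-01,2023-02,18,Program data
Lifeguard,app,British Columbia,canada,2021-01,2023-05,66,News brief
Better App,app,Canada,canada,2020-01,2020-12,0,Founders report no emergency responses initiated to date
iKeepr,app,Canada,canada,2022-01,2022-12,unknown,Developers do not record this figure
Ontario Overdose Prevention Line (OPL),hotline,Ontario,canada,2020-01,2020-12,3,Discontinued; replaced by NORS
BeSafe Brave,hybrid,Global,global,2020-01,2020-12,33,Publicly available call log data
Never Use Alone,hotline,USA,usa,2019-01,2021-12,28,Lives saved per 2021 statistics
The Canary - Prevent Overdose app,app,USA,usa,2018-01,2018-12,unknown,Founders state the figure is not yet recorded
Unity Philly,app,Philadelphia,usa,2019-03,2020-02,74,Program evaluation
Naxos Neighbors,app,USA,usa,unknown,unknown,0,0 lives saved; 214 downloads; 108 trained responders
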