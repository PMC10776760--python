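producer,retelling_index,text
llm,1,An older man is frequently alone because his wife is caring for their grandchild in another town. He has health issues but likes to chat with neighbors about politics. Neighbors listen kindly but politely decline due to work. He’s lonely and often watches out the window for the next chance to socialize
llm,2,"An older man is often alone as his wife is away caring for their grandchild. Despite his health issues, he enjoys discussing politics with neighbors who politely decline due to work. Feeling lonely, he watches out the window for a chance to socialize"
llm,3,"The story is about an older man who is frequently alone due to his wife caring for their grandchild. He has health problems but still likes to discuss politics with his neighbors, who decline due to work. He spends his days looking out the window, hoping for someone to talk to"
human,1,He is a older man but he has a caring wife but she is caring grandson in another town. He is very sick in health issues but he is alone in home so she is needed spend time with her husband she is working or interested in political views but he is don’t like to political views he is very lonely
human,2,"There is an older man who is unwell and he needs his wife to take care of him, but she is busy to care for an ill grandson who lives in another town. So, the wife does her best to spend time with both but because of the different political beliefs she and her husband hold, they spend so much time arguing that she prefers to spend time with her grandson"
human,3,"There is this wife who takes care of her husband because he is sick. She also takes care of an ill grandson that lives in another town. She tries her best to take care of both. However, her husband and her fight over politics so she prefers to spend more of her time with the grandson"
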